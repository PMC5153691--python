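"""Rigid/relaxed scoring of an output matrix against a gold standard.

Every extracted value is compared with a gold standard matrix (GSM)
value and assigned a pair of hit scores in {0, 0.5, 1}:

====  =====================================================  =====  =======
rule  condition                                              rigid  relaxed
====  =====================================================  =====  =======
1     negation polarity differs (or wrong value)               0      0
2     all structured fields match                              1      1
3     main values and negations match, other fields differ     0.5    1
4     extracted main contains the GSM main plus extra
      surrounding tokens ("Most strains ferment arbutin"
      vs "arbutin")                                            0.5    1
5     mains partially match (extracted is a strict token
      subset, or the token sets merely overlap)                0.5    0.5
6     otherwise                                                0      0
====  =====================================================  =====  =======

The relaxed score therefore forgives modifier/unit mismatches whenever
the main value and the negation agree; note the deliberate asymmetry
between rules 4 and 5 — extra tokens around a correct value cost only
rigid credit, a truncated value costs both.

For cells with several values, each extracted value is aligned one-to-one
with a GSM value so as to maximize the total relaxed score (ties broken
toward the higher rigid sum), and the cell's hit score is the sum over
aligned pairs.  Unmatched values on either side count in the respective
denominators.  Per character, over all taxa::

    P = sum of hit scores / number of extracted values
    R = sum of hit scores / number of GSM values
    F1 = 2PR / (P + R)

computed for the rigid and the relaxed hit scores separately; the
overall accuracy is the total relaxed hit sum divided by the total
number of GSM values.  Cells empty in both matrices are skipped.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from .characters import CHARACTER_IDS, CHARACTERS_BY_ID
from .extract_numeric import parse_numeric_range, standardize_unit
from .matrix_builder import TaxonCharacterMatrix
from .values import StructuredValue, serialize_structured_value


@dataclass(frozen=True)
class PairScore:
    rigid: float
    relaxed: float

    def __post_init__(self) -> None:
        if self.rigid not in (0, 0.5, 1) or self.relaxed not in (0, 0.5, 1):
            raise ValueError("hit scores must be 0, 0.5 or 1")
        if self.relaxed < self.rigid:
            raise ValueError("relaxed score cannot be below rigid score")


@dataclass
class CellScore:
    hit_sum_rigid: float = 0.0
    hit_sum_relaxed: float = 0.0
    n_extracted: int = 0
    n_gsm: int = 0


# ---------------------------------------------------------------------------
# pair scoring

_NEG_PREFIX = re.compile(r"^(no |not |neither |non-|non )", re.IGNORECASE)
_PUNCT_EDGE = re.compile(r"^[\s.,;:]+|[\s.,;:]+$")


def _norm(text: str) -> str:
    return " ".join(text.lower().split())


def _tokens(text: str) -> tuple[str, ...]:
    return tuple(
        t for t in (_PUNCT_EDGE.sub("", w) for w in _norm(text).split()) if t
    )


def _polarity(v: StructuredValue) -> bool:
    return bool(v.negation.strip()) or bool(_NEG_PREFIX.match(v.main_value))


def _main_core(v: StructuredValue) -> str:
    # polarity is compared separately; a leading cue is not part of the main
    return _NEG_PREFIX.sub("", _norm(v.main_value)).strip()


def _mains_equal(ext: StructuredValue, gsm: StructuredValue, kind: str) -> bool:
    if kind == "numeric":
        a = parse_numeric_range(ext.main_value)
        b = parse_numeric_range(gsm.main_value)
        if a is not None and b is not None:
            return (a.low, a.high) == (b.low, b.high)
    return _main_core(ext) == _main_core(gsm)


def _other_fields_equal(ext: StructuredValue, gsm: StructuredValue,
                        kind: str) -> bool:
    if kind == "numeric":
        if standardize_unit(ext.unit) != standardize_unit(gsm.unit):
            return False
    elif _norm(ext.unit) != _norm(gsm.unit):
        return False
    return (_norm(ext.modifier) == _norm(gsm.modifier)
            and _norm(ext.sub_character) == _norm(gsm.sub_character))


def _is_subsequence(inner: tuple[str, ...], outer: tuple[str, ...]) -> bool:
    it = iter(outer)
    return all(tok in it for tok in inner)


def score_value_pair(
    ext: StructuredValue, gsm: StructuredValue, kind: str = "categorical"
) -> PairScore:
    """Rigid/relaxed hit scores for one extracted vs one GSM value."""
    if _polarity(ext) != _polarity(gsm):
        return PairScore(0, 0)  # rule 1
    if _mains_equal(ext, gsm, kind):
        if _other_fields_equal(ext, gsm, kind):
            return PairScore(1, 1)  # rule 2
        return PairScore(0.5, 1)  # rule 3
    ext_t, gsm_t = _tokens(_main_core(ext)), _tokens(_main_core(gsm))
    if not ext_t or not gsm_t:
        return PairScore(0, 0)
    if len(ext_t) > len(gsm_t) and _is_subsequence(gsm_t, ext_t):
        return PairScore(0.5, 1)  # rule 4: extra surrounding tokens
    ext_set, gsm_set = set(ext_t), set(gsm_t)
    if ext_set < gsm_set or (ext_set & gsm_set
                             and not ext_set >= gsm_set):
        return PairScore(0.5, 0.5)  # rule 5: partial match
    return PairScore(0, 0)  # rule 6


# ---------------------------------------------------------------------------
# cell alignment

Overrides = dict[tuple[str, str], float]  # (ext serialized, gsm serialized)


def align_and_score(
    ext: list[StructuredValue],
    gsm: list[StructuredValue],
    kind: str = "categorical",
    overrides: Overrides | None = None,
) -> CellScore:
    """One-to-one assignment maximizing the total relaxed score (rigid
    sum breaks ties); unmatched values score 0 but count in n."""
    cell = CellScore(n_extracted=len(ext), n_gsm=len(gsm))
    if not ext or not gsm:
        return cell
    pair = [[score_value_pair(e, g, kind) for g in gsm] for e in ext]
    if overrides:
        for i, e in enumerate(ext):
            for j, g in enumerate(gsm):
                key = (serialize_structured_value(e),
                       serialize_structured_value(g))
                if key in overrides:
                    relaxed = overrides[key]
                    pair[i][j] = PairScore(min(pair[i][j].rigid, relaxed),
                                           relaxed)
    # weight relaxed far above rigid so the assignment is lexicographic
    weights = np.array(
        [[p.relaxed * 1024 + p.rigid for p in row] for row in pair]
    )
    rows, cols = linear_sum_assignment(weights, maximize=True)
    for i, j in zip(rows, cols):
        cell.hit_sum_rigid += pair[i][j].rigid
        cell.hit_sum_relaxed += pair[i][j].relaxed
    return cell


# ---------------------------------------------------------------------------
# report


@dataclass
class CharacterScore:
    rigid_sum: float = 0.0
    relaxed_sum: float = 0.0
    n_extracted: int = 0
    n_gsm: int = 0

    def _prf(self, hits: float) -> tuple[float, float, float]:
        p = hits / self.n_extracted if self.n_extracted else 0.0
        r = hits / self.n_gsm if self.n_gsm else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        return p, r, f1

    @property
    def rigid_prf(self) -> tuple[float, float, float]:
        return self._prf(self.rigid_sum)

    @property
    def relaxed_prf(self) -> tuple[float, float, float]:
        return self._prf(self.relaxed_sum)


@dataclass
class EvalReport:
    per_character: dict[str, CharacterScore]
    totals: CharacterScore

    @property
    def overall_accuracy(self) -> float:
        """Total relaxed hit sum over total GSM values."""
        if not self.totals.n_gsm:
            return 0.0
        return self.totals.relaxed_sum / self.totals.n_gsm


def compute_report(
    out: TaxonCharacterMatrix,
    gsm: TaxonCharacterMatrix,
    overrides: dict[tuple[str, str], Overrides] | None = None,
) -> EvalReport:
    """Score an output matrix against a gold standard matrix.

    Both matrices must cover the same taxa.  ``overrides`` optionally
    maps (taxon, character_id) to pair-level relaxed-score adjustments —
    the machine-readable stand-in for a manual re-review of imperfect
    matches.
    """
    missing = sorted(set(gsm.taxa) - set(out.taxa))
    extra = sorted(set(out.taxa) - set(gsm.taxa))
    if missing or extra:
        raise ValueError(
            f"taxon axes differ: missing from output {missing}, "
            f"unexpected in output {extra}"
        )
    per: dict[str, CharacterScore] = {cid: CharacterScore()
                                      for cid in CHARACTER_IDS}
    totals = CharacterScore()
    for taxon in gsm.taxa:
        for cid in CHARACTER_IDS:
            e, g = out.get(taxon, cid), gsm.get(taxon, cid)
            if not e and not g:
                continue  # not stated anywhere: no denominator contribution
            cell = align_and_score(
                e, g, CHARACTERS_BY_ID[cid].value_kind,
                (overrides or {}).get((taxon, cid)),
            )
            cs = per[cid]
            for obj in (cs, totals):
                obj.rigid_sum += cell.hit_sum_rigid
                obj.relaxed_sum += cell.hit_sum_relaxed
                obj.n_extracted += cell.n_extracted
                obj.n_gsm += cell.n_gsm
    return EvalReport(per_character=per, totals=totals)


def write_report(report: EvalReport, path: str | Path) -> None:
    """Per-character P/R/F1 (rigid and relaxed) plus a totals row, as CSV."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["character", "n_gsm", "n_extracted",
                    "P", "R", "F1", "Relaxed_P", "Relaxed_R", "Relaxed_F1"])
        for cid in CHARACTER_IDS:
            cs = report.per_character[cid]
            if not (cs.n_gsm or cs.n_extracted):
                continue
            w.writerow([
                CHARACTERS_BY_ID[cid].display_name, cs.n_gsm, cs.n_extracted,
                *(f"{x:.3f}" for x in cs.rigid_prf),
                *(f"{x:.3f}" for x in cs.relaxed_prf),
            ])
        t = report.totals
        w.writerow(["TOTAL", t.n_gsm, t.n_extracted,
                    *(f"{x:.3f}" for x in t.rigid_prf),
                    *(f"{x:.3f}" for x in t.relaxed_prf)])
        w.writerow(["overall_accuracy", "", "",
                    f"{report.overall_accuracy:.3f}", "", "", "", "", ""])


def load_overrides(path: str | Path) -> dict[tuple[str, str], Overrides]:
    """Read a TSV of (taxon, character, extracted, gsm, relaxed) rows."""
    out: dict[tuple[str, str], Overrides] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields")
            taxon, char, ext, gsm, relaxed = parts
            cid = CHARACTERS_BY_ID[char].id if char in CHARACTERS_BY_ID else (
                next(c.id for c in CHARACTERS_BY_ID.values()
                     if c.display_name == char)
            )
            out.setdefault((taxon, cid), {})[(ext, gsm)] = float(relaxed)
    return out
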