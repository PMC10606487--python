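"""Extreme-discordant sib-pair (EDSP) classification and selection.

A pair is *extreme discordant* when either

- the threshold rule holds: one sib is hypertensive (SBP > 139 or
  DBP > 85 mmHg) and the other hypotensive (SBP < 112 or DBP < 66 mmHg), or
- the difference rule holds: the within-pair differences exceed 25 mmHg
  systolic and 20 mmHg diastolic;

pairs that only clear the looser recruitment screen (differences above
15/14 mmHg) are *discordant*, and everything else *neither*.  All
comparisons are strict.  An alternative centile rule (opposite tails of a
reference blood-pressure distribution) is provided for percentile-based
designs.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np

from .models import (
    IndividualRecord,
    PairClassification,
    PhenotypeError,
    SelectionCriteria,
    SibPairRecord,
)

log = logging.getLogger(__name__)


def pulse_pressure(sbp: float, dbp: float) -> float:
    """Pulse pressure (mmHg), SBP - DBP; flags inverted readings."""
    if sbp < dbp:
        raise PhenotypeError(f"SBP {sbp} below DBP {dbp}")
    return sbp - dbp


def centile_thresholds(reference, lower_pct: float = 10.0,
                       upper_pct: float = 90.0) -> tuple[float, float]:
    """Nearest-rank percentile cut-offs from a reference sample."""
    ref = np.sort(np.asarray(reference, dtype=float).ravel())
    n = ref.size
    if n < 20:
        raise ValueError("reference sample must have >= 20 values")
    if not 0 < lower_pct < upper_pct < 100:
        raise ValueError("need 0 < lower_pct < upper_pct < 100")

    def nearest_rank(pct: float) -> float:
        rank = math.ceil(pct / 100.0 * n)
        return float(ref[max(rank, 1) - 1])

    return nearest_rank(lower_pct), nearest_rank(upper_pct)


def _require_bp(sib: IndividualRecord) -> tuple[float, float]:
    if sib.sbp is None or sib.dbp is None:
        raise PhenotypeError(
            f"({sib.family_id}, {sib.individual_id}): missing SBP/DBP")
    return sib.sbp, sib.dbp


def _affected_sib(sib1: IndividualRecord, sib2: IndividualRecord) -> str:
    """Higher-SBP sib; ties broken by higher DBP, then lexicographic id."""
    k1 = (-sib1.sbp, -sib1.dbp, sib1.individual_id)
    k2 = (-sib2.sbp, -sib2.dbp, sib2.individual_id)
    return sib1.individual_id if k1 <= k2 else sib2.individual_id


def classify_pair(sib1: IndividualRecord, sib2: IndividualRecord,
                  criteria: SelectionCriteria = SelectionCriteria(),
                  ) -> PairClassification:
    """Classify one sib pair against the discordance rules.

    Symmetric in its sib arguments except for ``affected_sib``.  The
    threshold rule is tested before the difference rule, so pairs
    satisfying both are attributed to the threshold rule.
    """
    s1, d1 = _require_bp(sib1)
    s2, d2 = _require_bp(sib2)
    c = criteria
    affected = _affected_sib(sib1, sib2)

    def is_high(s, d):
        return s > c.hi_sbp or d > c.hi_dbp

    def is_low(s, d):
        return s < c.lo_sbp or d < c.lo_dbp

    threshold = (is_high(s1, d1) and is_low(s2, d2)) or \
                (is_high(s2, d2) and is_low(s1, d1))
    ds, dd = abs(s1 - s2), abs(d1 - d2)
    combine = (lambda a, b: a or b) if c.or_rule else (lambda a, b: a and b)
    difference = combine(ds > c.diff_sbp, dd > c.diff_dbp)
    screen = combine(ds > c.screen_diff_sbp, dd > c.screen_diff_dbp)

    if threshold:
        return PairClassification("extreme_discordant", "threshold_rule",
                                  affected)
    if difference:
        return PairClassification("extreme_discordant", "difference_rule",
                                  affected)
    if screen:
        return PairClassification("discordant", "screen_only", affected)
    return PairClassification("neither", "none", affected)


def classify_pair_centile(sib1: IndividualRecord, sib2: IndividualRecord,
                          low_cut: float, high_cut: float,
                          phenotype: str = "sbp") -> PairClassification:
    """Centile rule: one sib above the upper cut and the other below the
    lower cut of the reference distribution for ``phenotype``."""
    _require_bp(sib1)
    _require_bp(sib2)
    x1 = sib1.phenotype(phenotype)
    x2 = sib2.phenotype(phenotype)
    affected = _affected_sib(sib1, sib2)
    extreme = (x1 > high_cut and x2 < low_cut) or \
              (x2 > high_cut and x1 < low_cut)
    if extreme:
        return PairClassification("extreme_discordant", "threshold_rule",
                                  affected)
    return PairClassification("neither", "none", affected)


def select_edsp(pairs: Sequence[SibPairRecord],
                criteria: SelectionCriteria = SelectionCriteria(),
                ) -> list[SibPairRecord]:
    """Classify every pair and keep the extreme discordant ones.

    Pairs with missing phenotypes are excluded and logged.  The returned
    list is in stable family-id order, and selection-funnel counts
    (families -> screened pairs -> EDSP pairs) are logged.
    """
    selected: list[SibPairRecord] = []
    n_screened = 0
    n_excluded = 0
    for pair in sorted(pairs, key=lambda p: p.family_id):
        try:
            cls = classify_pair(pair.sib1, pair.sib2, criteria)
        except PhenotypeError as exc:
            n_excluded += 1
            log.warning("pair %s excluded: %s", pair.family_id, exc)
            continue
        pair.classification = cls
        if cls.label in ("discordant", "extreme_discordant"):
            n_screened += 1
        if cls.label == "extreme_discordant":
            selected.append(pair)
    log.info("selection funnel: %d families -> %d screened pairs -> "
             "%d EDSP pairs (%d excluded for missing phenotypes)",
             len(pairs), n_screened, len(selected), n_excluded)
    return selected
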