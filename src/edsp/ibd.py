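"""Single-point IBD estimation for sib pairs without parental genotypes.

For a marker in Hardy-Weinberg equilibrium with known allele frequencies,
the probability of an observed unordered sib genotype pair factorises over
the number of alleles shared identically by descent (IBD = 0, 1, 2):

- IBD 0: the genotypes are independent HWE draws;
- IBD 1: one allele x is shared (drawn from the population), and each sib
  adds an independent random allele, so
  ``L1 = sum_x p_x * h(g1, x) * h(g2, x)`` where ``h({a,b}, x)`` is the
  probability of completing genotype {a,b} given shared allele x;
- IBD 2: the genotypes coincide and occur with their HWE probability.

The posterior combines these with the full-sib prior (1/4, 1/2, 1/4).
These closed forms are validated exhaustively against a brute-force
parental-enumeration oracle in the test suite.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

from .models import (
    EdspError,
    Genotype,
    IBDPosterior,
    IndividualRecord,
    MarkerMap,
    SIB_IBD_PRIOR,
    SibPairRecord,
    is_missing,
)

log = logging.getLogger(__name__)

#: per-marker allele code -> frequency
AlleleFrequencyTable = list[dict[int, float]]


class ImpossibleGenotypeError(EdspError):
    """Genotype pair with zero likelihood under every IBD state."""


def estimate_allele_frequencies(records: Sequence[IndividualRecord],
                                marker_map: MarkerMap) -> AlleleFrequencyTable:
    """Gene-counting allele frequency estimates per marker.

    Each non-missing genotype contributes two allele observations; missing
    genotypes are skipped.  Sib correlation is ignored (naive counting).
    """
    tables: AlleleFrequencyTable = []
    for m_idx, marker in enumerate(marker_map):
        counts: dict[int, int] = {}
        for rec in records:
            g = rec.genotypes[m_idx]
            if is_missing(g):
                continue
            for allele in g:
                counts[allele] = counts.get(allele, 0) + 1
        total = sum(counts.values())
        if total == 0:
            raise EdspError(
                f"marker {marker.name}: no genotyped individuals")
        tables.append({a: c / total for a, c in sorted(counts.items())})
    return tables


def _genotype_prob(g: Genotype, freqs: dict[int, float]) -> float:
    a, b = g
    return freqs[a] * freqs[b] * (1.0 if a == b else 2.0)


def _completion_prob(g: Genotype, x: int, freqs: dict[int, float]) -> float:
    """P(unordered genotype == g | one allele is x, other drawn from HWE)."""
    a, b = g
    if a == b:
        return freqs[a] if x == a else 0.0
    if x == a:
        return freqs[b]
    if x == b:
        return freqs[a]
    return 0.0


def pair_likelihoods_given_ibd(g1: Genotype, g2: Genotype,
                               freqs: dict[int, float],
                               ) -> Optional[tuple[float, float, float]]:
    """(L0, L1, L2) = P(unordered genotype pair | IBD = k) under HWE.

    Returns None (uninformative) when either genotype is missing; raises
    if a genotype carries an allele absent from the frequency table.
    """
    if is_missing(g1) or is_missing(g2):
        return None
    for g in (g1, g2):
        for allele in g:
            if allele not in freqs:
                raise EdspError(
                    f"allele {allele} absent from frequency table")
    l0 = _genotype_prob(g1, freqs) * _genotype_prob(g2, freqs)
    shared = set(g1) & set(g2)
    l1 = sum(freqs[x]
             * _completion_prob(g1, x, freqs)
             * _completion_prob(g2, x, freqs)
             for x in shared)
    l2 = _genotype_prob(g1, freqs) if tuple(sorted(g1)) == tuple(sorted(g2)) \
        else 0.0
    return (l0, l1, l2)


def ibd_posterior(g1: Genotype, g2: Genotype, freqs: dict[int, float],
                  prior: tuple[float, float, float] = SIB_IBD_PRIOR,
                  ) -> Optional[IBDPosterior]:
    """Posterior IBD distribution for one pair at one marker.

    None for missing genotypes; raises :class:`ImpossibleGenotypeError`
    when all three likelihoods vanish (corrupt data).
    """
    lik = pair_likelihoods_given_ibd(g1, g2, freqs)
    if lik is None:
        return None
    weighted = [p * l for p, l in zip(prior, lik)]
    total = sum(weighted)
    if total <= 0.0:
        raise ImpossibleGenotypeError(
            f"genotype pair {g1}/{g2} impossible under every IBD state")
    return IBDPosterior(*(w / total for w in weighted))


def pair_sharing_profile(pair: SibPairRecord, marker_map: MarkerMap,
                         freqs: AlleleFrequencyTable,
                         ) -> list[Optional[IBDPosterior]]:
    """Per-marker IBD posteriors for one pair, attached to the record.

    Markers with missing genotypes yield None (uninformative) and are
    excluded from downstream tests for that pair (pairwise-complete
    analysis).
    """
    profile: list[Optional[IBDPosterior]] = []
    for m_idx in range(len(marker_map)):
        g1 = pair.sib1.genotypes[m_idx]
        g2 = pair.sib2.genotypes[m_idx]
        profile.append(ibd_posterior(g1, g2, freqs[m_idx]))
    if all(p is None for p in profile):
        log.warning("pair %s: no informative markers", pair.family_id)
    pair.posteriors = profile
    return profile
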