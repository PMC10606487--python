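"""Cohort simulator: nuclear families with a biallelic QTL, linked
multi-allelic markers and SBP/DBP phenotypes, with true IBD recorded.

Transmission tracks grandparental origin jointly at the QTL and each
marker: a gamete recombines between the QTL and a marker with probability
theta, and markers are conditionally independent given the QTL
(single-point simulation).  True IBD at a locus is the number of meioses
(paternal, maternal) in which the two sibs received the same grandparental
allele.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .models import (
    MISSING_GENOTYPE,
    IndividualRecord,
    MarkerDef,
    SibPairRecord,
    SimulatedCohort,
    TraitModel,
)

#: cohort age distribution (years), mean +/- SD of the studied population
AGE_MEAN, AGE_SD, AGE_MIN = 39.8, 7.8, 18.0


def simulate_reference_sample(n: int, model: TraitModel, seed: int) -> np.ndarray:
    """Draw ``n`` unselected (SBP, DBP) pairs from the population model.

    Emulates a large healthy reference sample used to define blood-pressure
    centiles.  Returns an (n, 2) array with columns SBP, DBP.
    """
    if n < 2:
        raise ValueError("reference sample needs n >= 2")
    rng = np.random.default_rng(seed)
    p = model.qtl_allele_freq
    g = (rng.random((n, 2)) < p).sum(axis=1)  # QTL genotype 0/1/2
    sbp = np.asarray(model.genotype_means("sbp"))[g]
    dbp = np.asarray(model.genotype_means("dbp"))[g]
    sbp = model.mean_sbp + sbp + rng.normal(0.0, 1.0, n) * model.polygenic_sd_sbp
    dbp = model.mean_dbp + dbp + rng.normal(0.0, 1.0, n) * model.polygenic_sd_dbp
    e_sbp, e_dbp = _bivariate_env(model, n, rng)
    return np.column_stack([sbp + e_sbp, dbp + e_dbp])


def _bivariate_env(model: TraitModel, n: int, rng: np.random.Generator):
    """Environmental deviates for SBP and DBP with the model correlation."""
    c = model.env_corr_sbp_dbp
    z1 = rng.normal(0.0, 1.0, n)
    z2 = rng.normal(0.0, 1.0, n)
    e_sbp = model.env_sd_sbp * z1
    e_dbp = model.env_sd_dbp * (c * z1 + np.sqrt(max(0.0, 1.0 - c * c)) * z2)
    return e_sbp, e_dbp


def simulate_pair_arrays(
    model: TraitModel,
    markers: list[MarkerDef],
    n_pairs: int,
    rng: np.random.Generator,
) -> dict:
    """Vectorised engine behind :func:`simulate_families`.

    Returns a dict of numpy arrays over ``n_pairs`` families:

    - ``qtl_g1``, ``qtl_g2``: sib QTL genotypes (count of high alleles, 0-2)
    - ``sbp1/sbp2/dbp1/dbp2``: sib phenotypes (mmHg)
    - ``ibd_qtl``: true IBD count at the QTL
    - per marker ``m``: ``marker_g1[m]``/``marker_g2[m]`` (n, 2) sorted
      allele codes (1-based), ``ibd_marker[m]``, and parental genotypes
      ``father_m[m]``/``mother_m[m]``
    - ``age1/age2`` (years), ``sex1/sex2`` (1 = male, 2 = female)
    """
    n = n_pairs
    p = model.qtl_allele_freq
    ar = np.arange(n)

    father_q = rng.random((n, 2)) < p
    mother_q = rng.random((n, 2)) < p
    # grandparental origin of the QTL allele in each of the 4 meioses
    of1, of2 = rng.integers(0, 2, n), rng.integers(0, 2, n)
    om1, om2 = rng.integers(0, 2, n), rng.integers(0, 2, n)
    qtl_g1 = father_q[ar, of1].astype(int) + mother_q[ar, om1].astype(int)
    qtl_g2 = father_q[ar, of2].astype(int) + mother_q[ar, om2].astype(int)
    ibd_qtl = (of1 == of2).astype(int) + (om1 == om2).astype(int)

    out = {
        "qtl_g1": qtl_g1, "qtl_g2": qtl_g2, "ibd_qtl": ibd_qtl,
        "father_q": father_q, "mother_q": mother_q,
        "marker_g1": [], "marker_g2": [], "ibd_marker": [],
        "father_m": [], "mother_m": [],
    }

    for marker in markers:
        freqs = np.asarray(marker.allele_freqs)
        fa = rng.choice(marker.n_alleles, size=(n, 2), p=freqs) + 1
        mo = rng.choice(marker.n_alleles, size=(n, 2), p=freqs) + 1
        # marker origin = QTL origin, flipped on recombination
        t = marker.theta
        mf1 = of1 ^ (rng.random(n) < t)
        mf2 = of2 ^ (rng.random(n) < t)
        mm1 = om1 ^ (rng.random(n) < t)
        mm2 = om2 ^ (rng.random(n) < t)
        g1 = np.sort(np.column_stack([fa[ar, mf1], mo[ar, mm1]]), axis=1)
        g2 = np.sort(np.column_stack([fa[ar, mf2], mo[ar, mm2]]), axis=1)
        out["marker_g1"].append(g1)
        out["marker_g2"].append(g2)
        out["ibd_marker"].append(
            (mf1 == mf2).astype(int) + (mm1 == mm2).astype(int))
        out["father_m"].append(np.sort(fa, axis=1))
        out["mother_m"].append(np.sort(mo, axis=1))

    means_s = np.asarray(model.genotype_means("sbp"))
    means_d = np.asarray(model.genotype_means("dbp"))
    half = 1.0 / np.sqrt(2.0)
    shared_s = rng.normal(0.0, model.polygenic_sd_sbp * half, n)
    shared_d = rng.normal(0.0, model.polygenic_sd_dbp * half, n)
    own_s1 = rng.normal(0.0, model.polygenic_sd_sbp * half, n)
    own_s2 = rng.normal(0.0, model.polygenic_sd_sbp * half, n)
    own_d1 = rng.normal(0.0, model.polygenic_sd_dbp * half, n)
    own_d2 = rng.normal(0.0, model.polygenic_sd_dbp * half, n)
    e_s1, e_d1 = _bivariate_env(model, n, rng)
    e_s2, e_d2 = _bivariate_env(model, n, rng)

    out["sbp1"] = model.mean_sbp + means_s[qtl_g1] + shared_s + own_s1 + e_s1
    out["sbp2"] = model.mean_sbp + means_s[qtl_g2] + shared_s + own_s2 + e_s2
    out["dbp1"] = model.mean_dbp + means_d[qtl_g1] + shared_d + own_d1 + e_d1
    out["dbp2"] = model.mean_dbp + means_d[qtl_g2] + shared_d + own_d2 + e_d2

    out["age1"] = np.maximum(AGE_MIN, rng.normal(AGE_MEAN, AGE_SD, n))
    out["age2"] = np.maximum(AGE_MIN, rng.normal(AGE_MEAN, AGE_SD, n))
    out["sex1"] = rng.integers(1, 3, n)
    out["sex2"] = rng.integers(1, 3, n)
    return out


def simulate_families(
    n_families: int,
    model: TraitModel,
    markers: list[MarkerDef],
    seed: int,
) -> SimulatedCohort:
    """Simulate nuclear families of two parents and two genotyped sibs."""
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if not markers:
        raise ValueError("marker list must not be empty")
    rng = np.random.default_rng(seed)
    arr = simulate_pair_arrays(model, markers, n_families, rng)

    sex_code = {1: "male", 2: "female"}
    individuals: list[IndividualRecord] = []
    pairs: list[SibPairRecord] = []
    n_m = len(markers)
    for i in range(n_families):
        fam = f"F{i + 1:04d}"
        father = IndividualRecord(
            family_id=fam, individual_id="P1", sex="male",
            genotypes=[tuple(arr["father_m"][m][i]) for m in range(n_m)])
        mother = IndividualRecord(
            family_id=fam, individual_id="P2", sex="female",
            genotypes=[tuple(arr["mother_m"][m][i]) for m in range(n_m)])
        sibs = []
        for s, tag in ((1, "S1"), (2, "S2")):
            sibs.append(IndividualRecord(
                family_id=fam, individual_id=tag,
                father_id="P1", mother_id="P2",
                sex=sex_code[int(arr[f"sex{s}"][i])],
                age=float(arr[f"age{s}"][i]),
                sbp=float(arr[f"sbp{s}"][i]),
                dbp=float(arr[f"dbp{s}"][i]),
                genotypes=[tuple(arr[f"marker_g{s}"][m][i])
                           for m in range(n_m)]))
        individuals.extend([father, mother, *sibs])
        pairs.append(SibPairRecord(
            family_id=fam, sib1=sibs[0], sib2=sibs[1],
            true_ibd_qtl=int(arr["ibd_qtl"][i]),
            true_ibd_markers=[int(arr["ibd_marker"][m][i])
                              for m in range(n_m)]))
    return SimulatedCohort(individuals=individuals, sib_pairs=pairs,
                           seed=seed, model=model, markers=list(markers))


def mask_parents(cohort: SimulatedCohort) -> SimulatedCohort:
    """Remove parental genotypes, emulating an offspring-only study.

    Sib records (and true IBD) are shared, not copied, so offspring data
    are untouched; masking is idempotent.
    """
    masked = []
    for ind in cohort.individuals:
        if ind.father_id == "0":  # founder
            masked.append(replace(
                ind, genotypes=[MISSING_GENOTYPE] * len(ind.genotypes)))
        else:
            masked.append(ind)
    return SimulatedCohort(individuals=masked, sib_pairs=cohort.sib_pairs,
                           seed=cohort.seed, model=cohort.model,
                           markers=cohort.markers)
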