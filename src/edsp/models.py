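"""Domain types shared across the pipeline.

The analysis unit throughout is the genotyped sibling pair: two full sibs
with systolic/diastolic blood pressure (SBP/DBP) phenotypes and unordered
multi-allelic marker genotypes.  Pulse pressure (PP) is derived as
SBP - DBP.  Identity-by-descent (IBD) sharing at a locus is 0, 1 or 2
alleles with the unconditional full-sib prior (1/4, 1/2, 1/4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

#: unordered genotype, stored smaller-allele-first; (0, 0) means missing
Genotype = tuple[int, int]

MISSING_GENOTYPE: Genotype = (0, 0)

#: unconditional IBD prior for full sibs over 0/1/2 shared alleles
SIB_IBD_PRIOR = (0.25, 0.5, 0.25)

#: variance of the IBD proportion (0, 1/2, 1) under the full-sib prior
NULL_PI_VARIANCE = 0.125


class EdspError(Exception):
    """Base class for package errors."""


class FormatError(EdspError):
    """Malformed on-disk input."""


class PhenotypeError(EdspError):
    """Inconsistent or missing phenotype values."""


def sort_genotype(a: int, b: int) -> Genotype:
    return (a, b) if a <= b else (b, a)


def is_missing(g: Genotype) -> bool:
    return g[0] == 0 or g[1] == 0


@dataclass(frozen=True)
class TraitModel:
    """Biometric model for SBP/DBP in full sibs.

    A single biallelic quantitative trait locus (QTL) with high allele Q at
    frequency ``qtl_allele_freq`` contributes genotype means -a, d, +a
    (qq/Qq/QQ) to each trait; on top sit a shared polygenic component
    (full-sib covariance = half the polygenic variance) and an individual
    environmental deviate.  All effects are in mmHg.
    """

    qtl_allele_freq: float = 0.5
    additive_effect_sbp: float = 13.94
    additive_effect_dbp: float = 10.07
    dominance_sbp: float = 0.0
    dominance_dbp: float = 0.0
    polygenic_sd_sbp: float = 9.86
    polygenic_sd_dbp: float = 7.12
    env_sd_sbp: float = 11.38
    env_sd_dbp: float = 8.22
    mean_sbp: float = 125.0
    mean_dbp: float = 77.0
    env_corr_sbp_dbp: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.qtl_allele_freq < 1.0:
            raise ValueError("qtl_allele_freq must be in (0, 1)")
        for name in ("polygenic_sd_sbp", "polygenic_sd_dbp",
                     "env_sd_sbp", "env_sd_dbp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 <= self.env_corr_sbp_dbp <= 1.0:
            raise ValueError("env_corr_sbp_dbp must be in [-1, 1]")

    # --- variance bookkeeping -------------------------------------------

    def genotype_means(self, trait: str) -> tuple[float, float, float]:
        """Deviations from the trait mean for genotypes qq, Qq, QQ."""
        a = getattr(self, f"additive_effect_{trait}")
        d = getattr(self, f"dominance_{trait}")
        return (-a, d, a)

    def qtl_variance(self, trait: str) -> float:
        p = self.qtl_allele_freq
        q = 1.0 - p
        a = getattr(self, f"additive_effect_{trait}")
        d = getattr(self, f"dominance_{trait}")
        va = 2.0 * p * q * (a + d * (q - p)) ** 2
        vd = (2.0 * p * q * d) ** 2
        return va + vd

    def qtl_mean_shift(self, trait: str) -> float:
        """Population mean of the genotype-mean component."""
        p = self.qtl_allele_freq
        q = 1.0 - p
        a = getattr(self, f"additive_effect_{trait}")
        d = getattr(self, f"dominance_{trait}")
        return a * (p - q) + 2.0 * p * q * d

    def population_variance(self, trait: str) -> float:
        poly = getattr(self, f"polygenic_sd_{trait}")
        env = getattr(self, f"env_sd_{trait}")
        return self.qtl_variance(trait) + poly**2 + env**2

    @classmethod
    def from_variance_fractions(
        cls,
        qtl_frac_sbp: float = 0.3,
        qtl_frac_dbp: float = 0.3,
        polygenic_frac: float = 0.3,
        qtl_allele_freq: float = 0.5,
        sd_sbp: float = 18.0,
        sd_dbp: float = 13.0,
        mean_sbp: float = 125.0,
        mean_dbp: float = 77.0,
        env_corr_sbp_dbp: float = 0.5,
    ) -> "TraitModel":
        """Build a purely additive model from variance fractions.

        The additive effect solves V_qtl = 2p(1-p) a^2 for the requested
        fraction of total trait variance; the environmental fraction is the
        remainder.
        """
        p = qtl_allele_freq
        if not 0 < p < 1:
            raise ValueError("qtl_allele_freq must be in (0, 1)")
        for frac, label in ((qtl_frac_sbp, "qtl_frac_sbp"),
                            (qtl_frac_dbp, "qtl_frac_dbp"),
                            (polygenic_frac, "polygenic_frac")):
            if not 0 <= frac < 1:
                raise ValueError(f"{label} must be in [0, 1)")
        if qtl_frac_sbp + polygenic_frac >= 1 or qtl_frac_dbp + polygenic_frac >= 1:
            raise ValueError("variance fractions must sum below 1")

        def a_for(frac: float, sd: float) -> float:
            return math.sqrt(frac * sd**2 / (2.0 * p * (1.0 - p)))

        return cls(
            qtl_allele_freq=p,
            additive_effect_sbp=a_for(qtl_frac_sbp, sd_sbp),
            additive_effect_dbp=a_for(qtl_frac_dbp, sd_dbp),
            polygenic_sd_sbp=math.sqrt(polygenic_frac) * sd_sbp,
            polygenic_sd_dbp=math.sqrt(polygenic_frac) * sd_dbp,
            env_sd_sbp=math.sqrt(1.0 - qtl_frac_sbp - polygenic_frac) * sd_sbp,
            env_sd_dbp=math.sqrt(1.0 - qtl_frac_dbp - polygenic_frac) * sd_dbp,
            mean_sbp=mean_sbp,
            mean_dbp=mean_dbp,
            env_corr_sbp_dbp=env_corr_sbp_dbp,
        )


def default_trait_model() -> TraitModel:
    """Default cohort model: 125 +/- 18 / 77 +/- 13 mmHg, QTL 30% of
    variance, polygenes 30%, environment 40%."""
    return TraitModel.from_variance_fractions()


@dataclass(frozen=True)
class MarkerDef:
    """A multi-allelic marker and its single-point relation to the QTL."""

    name: str
    chromosome: str = "?"
    n_alleles: int = 8
    allele_freqs: tuple[float, ...] = ()
    theta: float = 0.5
    bp_range: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_alleles < 1:
            raise ValueError("n_alleles must be >= 1")
        if not 0.0 <= self.theta <= 0.5:
            raise ValueError("theta must be in [0, 0.5]")
        freqs = self.allele_freqs
        if not freqs:
            freqs = tuple([1.0 / self.n_alleles] * self.n_alleles)
            object.__setattr__(self, "allele_freqs", freqs)
        if len(freqs) != self.n_alleles:
            raise ValueError("allele_freqs length must equal n_alleles")
        if any(f < 0 for f in freqs) or abs(sum(freqs) - 1.0) > 1e-9:
            raise ValueError("allele_freqs must be a probability vector")

    @classmethod
    def equifrequent(cls, name: str, n_alleles: int, theta: float,
                     chromosome: str = "?") -> "MarkerDef":
        return cls(name=name, chromosome=chromosome, n_alleles=n_alleles,
                   theta=theta)

    def freq_dict(self) -> dict[int, float]:
        """Allele code (1-based) to frequency."""
        return {i + 1: f for i, f in enumerate(self.allele_freqs)}


class MarkerMap:
    """Ordered marker panel; order matches genotype columns."""

    def __init__(self, markers: Sequence[MarkerDef]):
        names = [m.name for m in markers]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")
        self._markers = list(markers)
        self._by_name = {m.name: m for m in self._markers}

    @property
    def markers(self) -> list[MarkerDef]:
        return list(self._markers)

    def __len__(self) -> int:
        return len(self._markers)

    def __iter__(self) -> Iterator[MarkerDef]:
        return iter(self._markers)

    def __getitem__(self, key) -> MarkerDef:
        if isinstance(key, str):
            return self._by_name[key]
        return self._markers[key]

    def index(self, name: str) -> int:
        return [m.name for m in self._markers].index(name)


@dataclass
class IndividualRecord:
    """One subject: pedigree links, phenotypes and marker genotypes."""

    family_id: str
    individual_id: str
    father_id: str = "0"
    mother_id: str = "0"
    sex: str = "unknown"  # male / female / unknown
    age: Optional[float] = None
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    genotypes: list[Genotype] = field(default_factory=list)

    @property
    def pp(self) -> Optional[float]:
        """Pulse pressure (mmHg)."""
        if self.sbp is None or self.dbp is None:
            return None
        return self.sbp - self.dbp

    def phenotype(self, name: str) -> Optional[float]:
        if name not in ("sbp", "dbp", "pp"):
            raise ValueError(f"unknown phenotype {name!r}")
        return getattr(self, name)

    @property
    def key(self) -> tuple[str, str]:
        return (self.family_id, self.individual_id)


@dataclass(frozen=True)
class IBDPosterior:
    """Posterior over 0/1/2 alleles shared IBD at one marker."""

    f0: float
    f1: float
    f2: float

    def __post_init__(self) -> None:
        total = self.f0 + self.f1 + self.f2
        if abs(total - 1.0) > 1e-9:
            raise ValueError("IBD posterior must sum to 1")
        if min(self.f0, self.f1, self.f2) < -1e-12:
            raise ValueError("IBD posterior probabilities must be >= 0")

    @property
    def pihat(self) -> float:
        """Estimated proportion of alleles shared IBD."""
        return 0.5 * self.f1 + self.f2

    @property
    def expected_shared(self) -> float:
        """Expected number of alleles shared IBD (= 2 * pihat)."""
        return self.f1 + 2.0 * self.f2


@dataclass(frozen=True)
class SelectionCriteria:
    """Extreme-discordance selection rules, in mmHg.

    A pair is extreme discordant when one sib is hypertensive
    (SBP > hi_sbp or DBP > hi_dbp) and the other hypotensive
    (SBP < lo_sbp or DBP < lo_dbp), or when the within-pair differences
    exceed diff_sbp and diff_dbp.  The looser screen_diff thresholds
    define ordinary discordance (the recruitment screen).  All
    inequalities are strict.  With ``or_rule`` the difference rules
    require either margin instead of both.
    """

    hi_sbp: float = 139.0
    hi_dbp: float = 85.0
    lo_sbp: float = 112.0
    lo_dbp: float = 66.0
    diff_sbp: float = 25.0
    diff_dbp: float = 20.0
    screen_diff_sbp: float = 15.0
    screen_diff_dbp: float = 14.0
    centile_lower: float = 10.0
    centile_upper: float = 90.0
    or_rule: bool = False

    def __post_init__(self) -> None:
        for name in ("hi_sbp", "hi_dbp", "lo_sbp", "lo_dbp", "diff_sbp",
                     "diff_dbp", "screen_diff_sbp", "screen_diff_dbp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lo_sbp >= self.hi_sbp or self.lo_dbp >= self.hi_dbp:
            raise ValueError("low thresholds must lie below high thresholds")
        if not self.centile_lower < self.centile_upper:
            raise ValueError("centile_lower must be below centile_upper")


@dataclass(frozen=True)
class PairClassification:
    label: str                 # extreme_discordant / discordant / neither
    which_rule: str            # threshold_rule / difference_rule / screen_only / none
    affected_sib: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label == "extreme_discordant" and self.which_rule not in (
                "threshold_rule", "difference_rule"):
            raise ValueError("extreme_discordant requires a strict rule")


@dataclass
class SibPairRecord:
    """A genotyped sibling pair and everything computed on it."""

    family_id: str
    sib1: IndividualRecord
    sib2: IndividualRecord
    true_ibd_qtl: Optional[int] = None
    true_ibd_markers: Optional[list[int]] = None
    posteriors: Optional[list[Optional[IBDPosterior]]] = None
    classification: Optional[PairClassification] = None

    def squared_difference(self, phenotype: str) -> float:
        x1 = self.sib1.phenotype(phenotype)
        x2 = self.sib2.phenotype(phenotype)
        if x1 is None or x2 is None:
            raise PhenotypeError(
                f"pair {self.family_id}: missing {phenotype} value")
        return (x1 - x2) ** 2


@dataclass
class SimulatedCohort:
    """Nuclear families with known-truth IBD at the QTL and every marker."""

    individuals: list[IndividualRecord]
    sib_pairs: list[SibPairRecord]
    seed: int
    model: TraitModel
    markers: list[MarkerDef]

    @property
    def marker_map(self) -> MarkerMap:
        return MarkerMap(self.markers)

    def offspring(self) -> list[IndividualRecord]:
        return [i for i in self.individuals if i.father_id != "0"]

    def parents(self) -> list[IndividualRecord]:
        return [i for i in self.individuals if i.father_id == "0"]
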