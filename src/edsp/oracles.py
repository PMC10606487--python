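"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the main analysis path: the IBD
oracle enumerates ordered parental genotypes and transmission patterns,
the regression oracle solves the normal equations directly, and the
sharing-LRT closed form evaluates the multinomial algebra for fully
informative pairs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .models import Genotype, SIB_IBD_PRIOR


def ibd_oracle(g1: Genotype, g2: Genotype,
               freqs: dict[int, float]) -> tuple[float, float, float]:
    """P(unordered sib genotype pair | IBD = k) by exhaustive enumeration.

    Enumerates every ordered parental genotype pair under Hardy-Weinberg
    and all 16 equally likely transmission patterns, labels each outcome's
    IBD count by grandparental origin, and conditions on the prior
    (1/4, 1/2, 1/4).  Refuses markers with more than 6 alleles.
    """
    alleles = sorted(freqs)
    if len(alleles) > 6:
        raise ValueError("oracle limited to <= 6 alleles")
    want1 = tuple(sorted(g1))
    want2 = tuple(sorted(g2))
    joint = [0.0, 0.0, 0.0]
    for fa in itertools.product(alleles, repeat=2):
        p_fa = freqs[fa[0]] * freqs[fa[1]]
        for mo in itertools.product(alleles, repeat=2):
            p_mo = freqs[mo[0]] * freqs[mo[1]]
            weight = p_fa * p_mo / 16.0
            for pf1, pm1, pf2, pm2 in itertools.product((0, 1), repeat=4):
                c1 = tuple(sorted((fa[pf1], mo[pm1])))
                c2 = tuple(sorted((fa[pf2], mo[pm2])))
                if c1 == want1 and c2 == want2:
                    k = int(pf1 == pf2) + int(pm1 == pm2)
                    joint[k] += weight
    return tuple(joint[k] / SIB_IBD_PRIOR[k] for k in range(3))


def normal_equations_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS coefficients (intercept first) via the normal equations."""
    design = np.column_stack([np.ones(len(y)), np.asarray(X)])
    xtx = design.T @ design
    return np.linalg.solve(xtx, design.T @ np.asarray(y))


def sharing_lrt_closed_form(counts: tuple[int, int, int]) -> float:
    """Likelihood-ratio statistic for fully informative pairs.

    With n_k pairs observed in IBD state k, the unconstrained MLE is the
    empirical proportion and ``LR = 2 * sum_k n_k log(n_k / (n * prior_k))``.
    """
    n = sum(counts)
    stat = 0.0
    for k, n_k in enumerate(counts):
        if n_k:
            stat += 2.0 * n_k * math.log(n_k / (n * SIB_IBD_PRIOR[k]))
    return stat
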