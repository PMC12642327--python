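"""Exact power and sample size for two-group detection-rate comparisons.

With n1 and n2 replicates per group and per-protein detection probabilities
p1 and p2, the number of replicates detecting the protein is binomial in each
group. The comparison is Fisher's exact test on the resulting 2x2 table —
the only exact test available at group sizes of 4–5 — and the power of the
design is obtained without approximation by enumerating all (n1+1) x (n2+1)
joint outcomes:

    power = sum over (k1, k2) of
            Binom(k1; n1, p1) * Binom(k2; n2, p2) * 1[p-value(k1, k2) < alpha]

The two-sided p-value uses the point-probability method (sum of all tables,
given the margins, whose conditional probability does not exceed the observed
table's); the doubling convention is available behind a flag. Rejection uses
strict inequality p < alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

Sidedness = Literal["two_sided", "one_sided"]

# relative tolerance when comparing table probabilities in the
# point-probability method, guarding against floating-point ties
_REL_TOL = 1e-9


@dataclass(frozen=True)
class PowerSpec:
    """A two-group binomial detection design."""

    p1: float
    n1: int
    p2: float
    n2: int
    alpha: float = 0.05
    sidedness: Sidedness = "two_sided"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p1 <= 1.0 and 0.0 <= self.p2 <= 1.0):
            raise ValueError("detection probabilities must lie in [0, 1]")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("group sizes must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def fisher_exact_p(
    k1: int,
    n1: int,
    k2: int,
    n2: int,
    sidedness: Sidedness = "two_sided",
    two_sided_method: Literal["point_probability", "doubling"] = "point_probability",
) -> float:
    """Exact conditional p-value for the 2x2 detection table.

    The table is [[k1, n1-k1], [k2, n2-k2]]. Conditioning on the margins,
    the first cell follows a hypergeometric distribution; the one-sided
    p-value is the upper tail in the direction k1/n1 > k2/n2, and the
    two-sided p-value follows the chosen convention.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError(f"invalid table ({k1}/{n1}, {k2}/{n2})")
    m = k1 + k2  # successes conditioned on
    dist = stats.hypergeom(M=n1 + n2, n=m, N=n1)
    if sidedness == "one_sided":
        return float(min(1.0, dist.sf(k1 - 1)))
    if sidedness != "two_sided":
        raise ValueError(f"unknown sidedness {sidedness!r}")
    if two_sided_method == "doubling":
        p = 2.0 * min(dist.cdf(k1), dist.sf(k1 - 1))
        return float(min(1.0, p))
    if two_sided_method != "point_probability":
        raise ValueError(f"unknown two-sided method {two_sided_method!r}")
    support = np.arange(max(0, m - n2), min(n1, m) + 1)
    pmf = dist.pmf(support)
    observed = dist.pmf(k1)
    return float(min(1.0, pmf[pmf <= observed * (1.0 + _REL_TOL)].sum()))


def rejection_region(
    n1: int, n2: int, alpha: float, sidedness: Sidedness = "two_sided"
) -> np.ndarray:
    """Boolean (n1+1) x (n2+1) array marking outcomes with p < alpha."""
    region = np.zeros((n1 + 1, n2 + 1), dtype=bool)
    for k1 in range(n1 + 1):
        for k2 in range(n2 + 1):
            region[k1, k2] = fisher_exact_p(k1, n1, k2, n2, sidedness) < alpha
    return region


def exact_power(spec: PowerSpec) -> float:
    """Exact rejection probability of the design, by full enumeration."""
    pmf1 = stats.binom.pmf(np.arange(spec.n1 + 1), spec.n1, spec.p1)
    pmf2 = stats.binom.pmf(np.arange(spec.n2 + 1), spec.n2, spec.p2)
    joint = np.outer(pmf1, pmf2)
    region = rejection_region(spec.n1, spec.n2, spec.alpha, spec.sidedness)
    return float(joint[region].sum())


def min_sample_size(
    p1: float,
    p2: float,
    alpha: float = 0.05,
    target_power: float = 0.8,
    sidedness: Sidedness = "two_sided",
    n_max: int = 50,
) -> dict:
    """Smallest equal per-group n whose exact power reaches the target.

    Searches n = 2 .. n_max in ascending order and returns a dict with keys
    ``n`` (the minimal n, or None when the target is not reached by n_max),
    ``reached`` (bool), ``target_power``, and ``power_curve`` — the full list
    of (n, power) pairs examined, since exact power of a discrete test is not
    monotone in n.
    """
    if p1 == p2:
        raise ValueError("p1 must differ from p2 for a sample-size target")
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    curve: list[tuple[int, float]] = []
    found: int | None = None
    for n in range(2, n_max + 1):
        pw = exact_power(PowerSpec(p1, n, p2, n, alpha, sidedness))
        curve.append((n, pw))
        if found is None and pw >= target_power:
            found = n
            break
    return {
        "n": found,
        "reached": found is not None,
        "target_power": target_power,
        "power_curve": curve,
    }
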