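"""Exact-moment uncertainty propagation for multiplicative dose models.

The dose equation is a product of independent factors (corrected signal,
calibration coefficient, correction factors).  For independent X and Y the
variance of the product is exact, with no linearisation::

    var(XY) = var(X) var(Y) + var(X) E(Y)^2 + var(Y) E(X)^2

and for (possibly correlated) sums::

    var(X + Y) = var(X) + var(Y) + 2 cov(X, Y)

Both identities hold for any distribution, so the propagated variance is an
exact second moment rather than a first-order (quadrature) approximation.
All quantities are carried as (expected value, variance) pairs; interfaces
quote relative expanded uncertainties at the 2-sigma level, the reporting
convention of clinical dosimetry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "UncertainQuantity",
    "CovarianceEntry",
    "var_product",
    "var_chain",
    "var_sum",
    "mean_signal_variance",
    "mc_oracle",
    "MCResult",
    "dose_uncertainty_budget",
]


@dataclass(frozen=True)
class UncertainQuantity:
    """A random quantity summarised by its first two moments."""

    expected: float
    variance: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError(f"variance must be >= 0, got {self.variance}")

    @classmethod
    def from_relative(
        cls, expected: float, rel_two_sigma_pct: float, label: str = ""
    ) -> "UncertainQuantity":
        """Build from a relative expanded uncertainty quoted as a 2-sigma percent."""
        sigma = abs(expected) * rel_two_sigma_pct / 200.0
        return cls(expected, sigma * sigma, label)

    @property
    def sigma(self) -> float:
        return math.sqrt(self.variance)

    @property
    def rel_two_sigma_pct(self) -> float:
        """Relative expanded (k=2) uncertainty in percent of the expected value."""
        if self.expected == 0:
            raise ZeroDivisionError("relative uncertainty undefined for zero mean")
        return 200.0 * self.sigma / abs(self.expected)

    def scaled(self, c: float, label: str | None = None) -> "UncertainQuantity":
        return UncertainQuantity(
            c * self.expected, c * c * self.variance, self.label if label is None else label
        )


@dataclass(frozen=True)
class CovarianceEntry:
    """Covariance between two labelled quantities; must satisfy Cauchy-Schwarz."""

    label_a: str
    label_b: str
    covariance: float
    var_a: float = field(default=math.inf)
    var_b: float = field(default=math.inf)

    def __post_init__(self) -> None:
        bound = math.sqrt(self.var_a * self.var_b)
        if abs(self.covariance) > bound * (1 + 1e-12):
            raise ValueError(
                f"covariance {self.covariance} violates Cauchy-Schwarz bound {bound}"
            )


def var_product(x: UncertainQuantity, y: UncertainQuantity) -> UncertainQuantity:
    """Exact variance of the product of two independent quantities.

    var(XY) = var(X)var(Y) + var(X)E(Y)^2 + var(Y)E(X)^2.  The first term is
    what quadrature omits; it makes the exact variance strictly larger
    whenever both inputs are uncertain.
    """
    ex, ey = x.expected, y.expected
    vx, vy = x.variance, y.variance
    return UncertainQuantity(
        ex * ey,
        vx * vy + vx * ey * ey + vy * ex * ex,
        label=_join_labels(x.label, y.label),
    )


def var_chain(factors: Sequence[UncertainQuantity]) -> UncertainQuantity:
    """Variance of a product of mutually independent factors.

    Applies ``var_product`` recursively (X = first factor, Y = product of the
    rest).  The result is invariant to the fold order because the exact
    product moments are symmetric.
    """
    if len(factors) == 0:
        raise ValueError("var_chain requires at least one factor")
    out = factors[0]
    for f in factors[1:]:
        out = var_product(out, f)
    return out


def var_sum(x: UncertainQuantity, y: UncertainQuantity, cov: float = 0.0) -> UncertainQuantity:
    """Variance of a sum with explicit covariance: var(X)+var(Y)+2 cov."""
    bound = math.sqrt(x.variance * y.variance)
    if abs(cov) > bound * (1 + 1e-12):
        raise ValueError(f"covariance {cov} violates Cauchy-Schwarz bound {bound}")
    return UncertainQuantity(
        x.expected + y.expected,
        x.variance + y.variance + 2.0 * cov,
        label=_join_labels(x.label, y.label, op="+"),
    )


def mean_signal_variance(
    read_matrix: Sequence[Sequence[float]],
    read_correlation: float = 0.0,
    k_s: Sequence[UncertainQuantity] | None = None,
    read_variance: float | None = None,
) -> UncertainQuantity:
    """Moments of the pooled mean corrected signal across dosimeters.

    Repeated reads of one dosimeter share the latent true signal (and its
    element sensitivity), so they are correlated; reads of different
    dosimeters are independent.  Within a dosimeter the variance of the
    J-read mean follows from the sum identity with pairwise covariance
    ``rho * var``::

        var(mean_J) = (var / J) * (1 + (J - 1) rho)

    so full correlation (rho = 1) gives no 1/J reduction.  The per-dosimeter
    mean is then multiplied by its sensitivity factor via the exact product
    identity, and the independent per-dosimeter results are averaged.

    Parameters
    ----------
    read_matrix
        Per-dosimeter sequences of depletion-corrected reads (counts).
    read_correlation
        Correlation between any two reads of the same dosimeter
        (shared-latent-signal model).
    k_s
        Optional per-dosimeter sensitivity factors as uncertain quantities;
        defaults to exact unity.
    read_variance
        Per-read variance; if None, estimated per dosimeter from its reads
        (requires >= 2 reads for a nonzero estimate).
    """
    rows = [np.asarray(r, dtype=float) for r in read_matrix]
    if not rows:
        raise ValueError("read_matrix must contain at least one dosimeter")
    if not -1.0 <= read_correlation <= 1.0:
        raise ValueError("read_correlation must lie in [-1, 1]")
    if k_s is None:
        k_s = [UncertainQuantity(1.0, 0.0)] * len(rows)
    if len(k_s) != len(rows):
        raise ValueError("k_s length must match number of dosimeters")

    per_dosimeter: list[UncertainQuantity] = []
    for reads, ks in zip(rows, k_s):
        j = reads.size
        if j == 0:
            raise ValueError("each dosimeter needs at least one read")
        v = read_variance
        if v is None:
            v = float(np.var(reads, ddof=1)) if j > 1 else 0.0
        mean = UncertainQuantity(
            float(reads.mean()), (v / j) * (1.0 + (j - 1) * read_correlation)
        )
        per_dosimeter.append(var_product(mean, ks))

    n = len(per_dosimeter)
    pooled_mean = sum(q.expected for q in per_dosimeter) / n
    pooled_var = sum(q.variance for q in per_dosimeter) / (n * n)
    return UncertainQuantity(pooled_mean, pooled_var, label="mean_signal")


@dataclass(frozen=True)
class MCResult:
    """Sample moments from the Monte Carlo oracle, with standard errors."""

    mean: float
    variance: float
    se_mean: float
    se_variance: float
    n: int

    def as_quantity(self, label: str = "mc") -> UncertainQuantity:
        return UncertainQuantity(self.mean, self.variance, label)


_DISTRIBUTIONS: dict[str, Callable[..., np.ndarray]] = {
    "normal": lambda rng, n, mean, sigma: rng.normal(mean, sigma, n),
    "lognormal": lambda rng, n, mean, sigma: _lognormal_moments(rng, n, mean, sigma),
    "uniform": lambda rng, n, low, high: rng.uniform(low, high, n),
    "constant": lambda rng, n, value: np.full(n, float(value)),
}


def _lognormal_moments(rng: np.random.Generator, n: int, mean: float, sigma: float) -> np.ndarray:
    """Lognormal sample parameterised by its arithmetic mean and SD."""
    if mean <= 0:
        raise ValueError("lognormal mean must be positive")
    rel_var = (sigma / mean) ** 2
    s2 = math.log1p(rel_var)
    mu = math.log(mean) - 0.5 * s2
    return rng.lognormal(mu, math.sqrt(s2), n)


def mc_oracle(
    variables: dict[str, tuple],
    expression: Callable[[dict[str, np.ndarray]], np.ndarray],
    n: int = 1_000_000,
    seed: int = 20181113,
    correlation: dict[tuple[str, str], float] | None = None,
) -> MCResult:
    """Seeded Monte Carlo estimate of the moments of an expression.

    ``variables`` maps labels to distribution descriptors, e.g.
    ``{"x": ("normal", 1.0, 0.1)}``; ``expression`` combines the sampled
    arrays.  Pairs listed in ``correlation`` are sampled as normals with a
    Gaussian copula-free direct construction (only supported for normal
    marginals).  Returns sample mean and variance with their standard
    errors; with the same seed the output is bit-identical.
    """
    if n < 10_000:
        raise ValueError("mc_oracle requires n >= 10000 for stable moments")
    rng = np.random.default_rng(seed)
    samples: dict[str, np.ndarray] = {}
    correlated_done: set[str] = set()
    if correlation:
        for (a, b), rho in correlation.items():
            if not -1.0 <= rho <= 1.0:
                raise ValueError("correlation must lie in [-1, 1]")
            for lbl in (a, b):
                if variables[lbl][0] != "normal":
                    raise NotImplementedError(
                        "injected correlation supported for normal marginals only"
                    )
            _, ma, sa = variables[a]
            _, mb, sb = variables[b]
            z1 = rng.standard_normal(n)
            z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
            samples[a] = ma + sa * z1
            samples[b] = mb + sb * z2
            correlated_done.update((a, b))
    for label, desc in variables.items():
        if label in correlated_done:
            continue
        kind, *params = desc
        if kind not in _DISTRIBUTIONS:
            raise KeyError(f"unknown distribution {kind!r}; known: {sorted(_DISTRIBUTIONS)}")
        samples[label] = _DISTRIBUTIONS[kind](rng, n, *params)

    values = np.asarray(expression(samples), dtype=float)
    mean = float(values.mean())
    var = float(values.var(ddof=1))
    # SE of the sample variance from the fourth central moment (no normality assumed)
    m4 = float(((values - mean) ** 4).mean())
    se_var = math.sqrt(max(m4 - (n - 3) / (n - 1) * var * var, 0.0) / n)
    return MCResult(mean, var, math.sqrt(var / n), se_var, n)


def dose_uncertainty_budget(
    components: dict[str, float],
    expected: dict[str, float] | None = None,
) -> dict[str, float]:
    """Itemised relative-uncertainty budget for a multiplicative dose model.

    ``components`` maps factor names to relative 2-sigma percentages.  Each
    factor is centred on 1 (or on ``expected[name]``); the total is computed
    by the exact product-variance recursion, so it is never below the
    root-sum-square of the components.  Returns the per-component entries
    plus a ``"total"`` key, all as relative 2-sigma percentages.
    """
    if not components:
        raise ValueError("budget requires at least one component")
    expected = expected or {}
    factors = [
        UncertainQuantity.from_relative(expected.get(name, 1.0), rel, label=name)
        for name, rel in components.items()
    ]
    total = var_chain(factors)
    report = dict(components)
    report["total"] = total.rel_two_sigma_pct
    return report


def _join_labels(a: str, b: str, op: str = "*") -> str:
    if a and b:
        return f"{a}{op}{b}"
    return a or b
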