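"""Axon diameter statistics and the myelin g-ratio model.

White matter axon calibers are well described by a Gamma law; here the law is
parameterized by its mean ``mu`` (um) and variance ``sigma2`` (um^2) and
truncated to a physiological window (0.2--10 um by default) to exclude
unrealistically small or large fibers.  Diameters are drawn with a
Metropolis--Hastings random walk whose acceptance probability is forced to
zero outside the truncation window.

Each axon carries a myelin sheath.  The g-ratio (inner over outer fiber
diameter) grows logarithmically with caliber,

    g(d) = slope * log(d) + intercept,

so the outer, myelinated diameter is ``d / g(d)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GammaDiameterModel",
    "GRatioRelation",
    "AxonPopulation",
    "gamma_params",
    "build_population",
]


def gamma_params(mu: float, sigma2: float) -> tuple[float, float]:
    """Shape/scale parameters of the Gamma law with mean ``mu``, variance ``sigma2``.

    Returns ``(a, b)`` with ``a = (mu/sigma)**2`` and ``b = sigma2/mu`` so that
    ``Gamma(a, b)`` has mean ``a*b = mu`` and variance ``a*b**2 = sigma2``.
    """
    if mu <= 0:
        raise ValueError(f"mean diameter must be positive, got {mu}")
    if sigma2 <= 0:
        raise ValueError(f"diameter variance must be positive, got {sigma2}")
    return mu * mu / sigma2, sigma2 / mu


@dataclass(frozen=True)
class GammaDiameterModel:
    """Truncated Gamma law for inner axon diameters.

    Parameters
    ----------
    mu:
        Mean inner diameter (um) of the untruncated law.
    sigma2:
        Variance (um^2).  ``sigma2 = 0`` denotes the degenerate
        (monodisperse) case where every axon has diameter ``mu``.
    d_min, d_max:
        Hard truncation bounds (um); samples never fall outside.
    """

    mu: float
    sigma2: float
    d_min: float = 0.2
    d_max: float = 10.0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"mean diameter must be positive, got {self.mu}")
        if self.sigma2 < 0:
            raise ValueError(f"variance must be non-negative, got {self.sigma2}")
        if not 0 < self.d_min < self.mu < self.d_max:
            raise ValueError(
                f"need 0 < d_min < mu < d_max, got d_min={self.d_min}, "
                f"mu={self.mu}, d_max={self.d_max}"
            )

    @property
    def shape(self) -> float:
        return gamma_params(self.mu, self.sigma2)[0]

    @property
    def scale(self) -> float:
        return gamma_params(self.mu, self.sigma2)[1]

    def pdf(self, d):
        """Gamma density d^(a-1) exp(-d/b) / (Gamma(a) b^a); 0 for d <= 0.

        This is the untruncated density; the sampler applies the truncation
        window through the acceptance rule, which only changes the
        normalization constant, not the shape.
        """
        if self.sigma2 == 0:
            raise ValueError("degenerate model (sigma2=0) has no density")
        d = np.asarray(d, dtype=float)
        out = np.where(d > 0, stats.gamma.pdf(np.maximum(d, 1e-300), self.shape, scale=self.scale), 0.0)
        return out if out.ndim else float(out)

    def sample(self, n: int, seed: int | np.random.Generator = 0) -> np.ndarray:
        """Draw ``n`` inner diameters with a Metropolis--Hastings random walk.

        The chain starts at ``mu``, proposes Gaussian steps of standard
        deviation ``max(sigma, 0.25)`` um, and forces the acceptance
        probability to zero outside ``[d_min, d_max]``.  The first 1000
        accepted-or-rejected steps are discarded as burn-in and the chain is
        thinned by 5 to reduce autocorrelation.  Deterministic for a fixed
        seed.
        """
        if n < 1:
            raise ValueError(f"need n >= 1, got {n}")
        if self.sigma2 == 0:
            return np.full(n, self.mu, dtype=float)
        rng = np.random.default_rng(seed)
        burn_in, thin = 1000, 5
        steps = burn_in + thin * n
        prop_sd = max(math.sqrt(self.sigma2), 0.25)
        increments = rng.normal(0.0, prop_sd, size=steps)
        uniforms = rng.random(steps)
        a, b = self.shape, self.scale

        def log_density(d: float) -> float:
            return (a - 1.0) * math.log(d) - d / b

        current = self.mu
        log_cur = log_density(current)
        chain = np.empty(steps)
        for t in range(steps):
            proposal = current + increments[t]
            if self.d_min <= proposal <= self.d_max:
                log_prop = log_density(proposal)
                if log_prop - log_cur >= 0 or uniforms[t] < math.exp(log_prop - log_cur):
                    current, log_cur = proposal, log_prop
            chain[t] = current
        return chain[burn_in::thin][:n].copy()


@dataclass(frozen=True)
class GRatioRelation:
    """Logarithmic dependence of the g-ratio on inner axon diameter.

    ``g(d) = slope * log(d) + intercept``, clamped to ``[g_min, g_max]``.
    ``log_base`` may be 10 (default) or ``e``; base 10 keeps g < 1 over the
    whole physiological diameter range, whereas the natural log crosses 1
    near d = 9.4 um.  At d = 1 um the relation returns the intercept in
    either base.
    """

    slope: float = 0.220
    intercept: float = 0.508
    log_base: float = 10.0
    g_min: float = 0.10
    g_max: float = 0.99

    def __post_init__(self) -> None:
        if not 0 < self.g_min < self.g_max < 1:
            raise ValueError(f"need 0 < g_min < g_max < 1, got [{self.g_min}, {self.g_max}]")
        if self.log_base not in (10.0, 10, math.e):
            raise ValueError("log_base must be 10 or math.e")

    def g_ratio(self, d_inner):
        """Clamped g-ratio for inner diameter ``d_inner`` (um); vectorized."""
        d = np.asarray(d_inner, dtype=float)
        if np.any(d <= 0):
            raise ValueError("inner diameter must be positive")
        log_d = np.log10(d) if self.log_base in (10.0, 10) else np.log(d)
        g = np.clip(self.slope * log_d + self.intercept, self.g_min, self.g_max)
        return g if g.ndim else float(g)

    __call__ = g_ratio


@dataclass
class AxonPopulation:
    """A set of axons ready for packing.

    ``packing_diameters`` are the diameters the packing engine treats as hard
    disks: the outer (myelinated) diameters by default, since fibers touch at
    their myelin peripheries; the gap ``delta`` is the extra clearance imposed
    between those peripheries.
    """

    inner_diameters: np.ndarray
    g_ratios: np.ndarray
    outer_diameters: np.ndarray
    delta: float
    packing_diameters: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.inner_diameters = np.asarray(self.inner_diameters, dtype=float)
        self.g_ratios = np.asarray(self.g_ratios, dtype=float)
        self.outer_diameters = np.asarray(self.outer_diameters, dtype=float)
        if self.packing_diameters is None:
            self.packing_diameters = self.outer_diameters
        self.packing_diameters = np.asarray(self.packing_diameters, dtype=float)
        if self.delta < 0:
            raise ValueError(f"gap delta must be non-negative, got {self.delta}")
        n = len(self.inner_diameters)
        if not (len(self.g_ratios) == len(self.outer_diameters) == len(self.packing_diameters) == n):
            raise ValueError("per-axon arrays must have equal length")

    def __len__(self) -> int:
        return len(self.inner_diameters)


def build_population(
    inner_diameters,
    delta: float = 0.0,
    relation: GRatioRelation | None = None,
    pack_on: str = "outer",
) -> AxonPopulation:
    """Derive g-ratios and outer diameters and assemble an :class:`AxonPopulation`.

    Parameters
    ----------
    inner_diameters:
        Inner (unmyelinated) diameters in um, all positive.
    delta:
        Inter-fiber gap in um (clearance between packed-disk peripheries).
    relation:
        g-ratio model; defaults to :class:`GRatioRelation` defaults.
    pack_on:
        ``"outer"`` (default) packs the myelinated outer circles;
        ``"inner"`` packs the bare axon circles.
    """
    if pack_on not in ("outer", "inner"):
        raise ValueError(f"pack_on must be 'outer' or 'inner', got {pack_on!r}")
    relation = relation or GRatioRelation()
    inner = np.asarray(inner_diameters, dtype=float)
    if inner.ndim != 1 or len(inner) == 0:
        raise ValueError("inner_diameters must be a non-empty 1-D sequence")
    if np.any(inner <= 0):
        raise ValueError("all inner diameters must be positive")
    g = np.atleast_1d(relation.g_ratio(inner))
    outer = inner / g
    packing = outer if pack_on == "outer" else inner
    return AxonPopulation(
        inner_diameters=inner,
        g_ratios=g,
        outer_diameters=outer,
        delta=float(delta),
        packing_diameters=packing.copy(),
    )
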