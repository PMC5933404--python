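"""Deviating-model generation and SSD statistics.

The central idea: at least-squares convergence the parameter vector is
multivariate Gaussian with mean X_min and covariance B = A^-1.  With
A = Q D Q^T orthogonally diagonalized, S = Q D^(-1/2) is a square root of
B (S S^T = B), so

    X = X_min + S R

with R a vector of independent unit-variance deviates produces parameter
sets "at standard deviation" from the refined model.  R is drawn from a
truncated Gaussian (support [-4, 4], renormalized to unit variance) so that
no deviating model is a meaningless outlier.  Sample standard deviations
(SSDs) of any property over the ensemble estimate that property's
uncertainty; the SSD itself has a chi-distribution precision of roughly
1/sqrt(2(N-1)) — 16% for N = 20.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm

from .model import CrystalModel, ParameterVector, unpack_parameters
from .refine import CovarianceModel, NormalEquations

TRUNCATION_BOUND = 4.0

# variance of a standard normal truncated to [-b, b]
def truncated_variance(bound: float = TRUNCATION_BOUND) -> float:
    return 1.0 - 2.0 * bound * norm.pdf(bound) / (2.0 * norm.cdf(bound) - 1.0)


@dataclass
class SquareRootFactor:
    """S with S S^T = B, from the eigendecomposition of the normal matrix."""

    s: np.ndarray
    eigvals: np.ndarray        # eigenvalues of A (after flooring)
    eigvecs: np.ndarray
    floor_applied: int
    gof_scaled: bool
    index_map: list

    @property
    def n(self):
        return self.s.shape[0]

    def covariance(self):
        return self.s @ self.s.T


class NotPositiveDefiniteError(np.linalg.LinAlgError):
    pass


def covariance_sqrt(ne: NormalEquations, cov: CovarianceModel = None,
                    eigen_floor=1e-10, gof_scale=True) -> SquareRootFactor:
    """Square-root factor S = Q D^(-1/2) of B = A^(-1).

    Eigenvalues of A below ``eigen_floor`` times the largest are clamped
    (counted in ``floor_applied``); a significantly negative eigenvalue
    raises, naming the parameter with the largest leverage on the offending
    eigenvector.  When ``gof_scale`` and a covariance model with GOF != 1 is
    supplied, S is multiplied by the GOF so the sampled spread matches the
    scaled e.s.d.'s.
    """
    a = ne.a
    if not np.allclose(a, a.T, atol=1e-8 * max(1.0, np.abs(a).max())):
        raise ValueError("normal matrix must be symmetric")
    evals, q = np.linalg.eigh(a)
    vmax = float(np.max(evals))
    bad = evals < -1e-8 * vmax
    if np.any(bad):
        worst_vec = q[:, int(np.argmin(evals))]
        label = ne.index_map[int(np.argmax(np.abs(worst_vec)))]
        raise NotPositiveDefiniteError(
            f"normal matrix not positive semi-definite; worst leverage on "
            f"parameter {label}")
    floor = eigen_floor * vmax
    floored = int(np.sum(evals < floor))
    evals_c = np.maximum(evals, floor)
    s = q / np.sqrt(evals_c)[None, :]
    gof_scaled = False
    if gof_scale and cov is not None and cov.scaled:
        s = s * cov.gof
        gof_scaled = True
    return SquareRootFactor(s=s, eigvals=evals_c, eigvecs=q,
                            floor_applied=floored, gof_scaled=gof_scaled,
                            index_map=list(ne.index_map))


def truncated_gaussian(count, seed, bound=TRUNCATION_BOUND):
    """Unit-variance truncated-Gaussian deviates, deterministic given seed.

    Standard-normal draws outside [-bound, bound] are rejected; the
    survivors are divided by the truncated distribution's standard
    deviation, which restores exactly unit population variance (and widens
    the support to bound/sqrt(v_trunc) in standardized units).
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    out = np.empty(count)
    have = 0
    while have < count:
        draw = rng.normal(size=max(count - have, 16))
        keep = draw[np.abs(draw) <= bound]
        take = min(len(keep), count - have)
        out[have:have + take] = keep[:take]
        have += take
    return out / np.sqrt(truncated_variance(bound))


@dataclass
class DeviatingEnsemble:
    """N parameter vectors drawn around the refined X_min."""

    reference: ParameterVector
    members: list                  # list of ParameterVector
    seed: int
    truncation_bound: float
    renormalization: float         # 1/sqrt(v_trunc)
    sqrt_factor: SquareRootFactor = None

    @property
    def n(self):
        return len(self.members)

    def member_values(self):
        return np.array([m.values for m in self.members])

    def member_models(self, model: CrystalModel):
        """Unpack every member into a crystal model; negative kappas are a
        hard error (they indicate an ill-scaled covariance)."""
        out = []
        for i, pv in enumerate(self.members):
            for value, (label, kind, _) in zip(pv.values, pv.index_map):
                if kind in ("kappa", "kappa_prime") and value <= 0:
                    raise ValueError(
                        f"member {i}: unphysical {kind} = {value:.4f} "
                        f"for atom {label}")
            out.append(unpack_parameters(model, pv))
        return out


def generate_ensemble(x_min: ParameterVector, sqrt_factor: SquareRootFactor,
                      n, seed, bound=TRUNCATION_BOUND) -> DeviatingEnsemble:
    """Draw N deviating parameter vectors X = X_min + S R.

    One master seed spawns per-member substreams, so an ensemble is
    reproducible and can be extended without redrawing earlier members.
    """
    if n < 2:
        raise ValueError("need at least 2 deviating models")
    npar = len(x_min.values)
    streams = np.random.SeedSequence(seed).spawn(n)
    members = []
    for sub in streams:
        r = truncated_gaussian(npar, np.random.default_rng(sub), bound)
        values = x_min.values + sqrt_factor.s @ r
        members.append(ParameterVector(values=values,
                                       index_map=list(x_min.index_map)))
    return DeviatingEnsemble(
        reference=x_min, members=members, seed=seed, truncation_bound=bound,
        renormalization=1.0 / np.sqrt(truncated_variance(bound)),
        sqrt_factor=sqrt_factor)


# ---------------------------------------------------------------------------
# SSD statistics


@dataclass
class SSDReport:
    """Sample mean and standard deviation of one derived property."""

    label: str
    mean: float
    ssd: float
    n: int
    occurrence: int
    expected_relative_sd: float
    units: str = ""
    values: np.ndarray = field(default=None, repr=False)

    def format(self):
        from .formats import format_value_with_uncertainty
        return format_value_with_uncertainty(self.mean, self.ssd)


def sample_standard_deviation(values, label="property", units="") -> SSDReport:
    """SSD with the N-1 denominator, so that SSD*sqrt(N-1)/sigma follows a
    chi distribution with N-1 degrees of freedom for Gaussian properties."""
    values = np.asarray(values, float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 values for an SSD")
    mean = float(np.mean(values))
    ssd = float(np.sqrt(np.sum((values - mean) ** 2) / (n - 1)))
    return SSDReport(label=label, mean=mean, ssd=ssd, n=n, occurrence=n,
                     expected_relative_sd=expected_relative_sd_of_ssd(n),
                     units=units, values=values)


def expected_relative_sd_of_ssd(n, approximate=False) -> float:
    """Expected relative standard deviation of the SSD estimator at sample
    size N: sd(chi_nu)/E(chi_nu) with nu = N-1 (exact chi moments), or the
    1/sqrt(2(N-1)) large-N approximation."""
    if n < 2:
        raise ValueError("need N >= 2")
    nu = n - 1
    if approximate:
        return 1.0 / np.sqrt(2.0 * nu)
    # E(chi_nu) = sqrt(2) Gamma((nu+1)/2) / Gamma(nu/2); Var = nu - E^2
    log_mean = 0.5 * np.log(2.0) + gammaln((nu + 1) / 2.0) - gammaln(nu / 2.0)
    mean = np.exp(log_mean)
    var = nu - mean**2
    return float(np.sqrt(max(var, 0.0)) / mean)


def ensemble_property_report(ensemble: DeviatingEnsemble, property_fn,
                             model: CrystalModel = None, label="property",
                             units="", reference_value=None) -> SSDReport:
    """Evaluate a property on every member and reduce to an SSDReport.

    ``property_fn`` receives a member (a CrystalModel when ``model`` is
    given, else the raw ParameterVector) and returns a float or None
    ("not found", e.g. a critical point that vanished in that member).
    Members where the property is absent are excluded from the statistics
    but counted through ``occurrence``.
    """
    targets = (ensemble.member_models(model) if model is not None
               else ensemble.members)
    values = [property_fn(t) for t in targets]
    present = np.array([v for v in values if v is not None], float)
    occurrence = len(present)
    if occurrence < 2:
        return SSDReport(label=label, mean=float("nan"), ssd=float("nan"),
                         n=ensemble.n, occurrence=occurrence,
                         expected_relative_sd=float("nan"), units=units,
                         values=present)
    rep = sample_standard_deviation(present, label=label, units=units)
    rep.n = ensemble.n
    rep.occurrence = occurrence
    if reference_value is not None and rep.ssd > 0:
        # diagnostic mirrored from practice: the ensemble mean generally
        # falls within one SSD of the reference-model value
        rep.mean_minus_reference_over_ssd = \
            (rep.mean - reference_value) / rep.ssd
    return rep
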