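"""Droplet digital PCR quantification and Bayesian relative-mutation-dosage
(RMD) fetal genotype calling.

A maternal plasma cfDNA sample from a mother heterozygous (N/M) for a GCK
variant carries the variant allele at fraction 1/2 if the fetus is also
heterozygous, and at (1 - f)/2 if the fetus is homozygous wild type, where
f is the fetal fraction.  ddPCR partitions the sample into droplets; the
number of positive droplets per channel follows a binomial law whose
success probability is 1 - exp(-lambda * theta) under Poisson loading at
mean lambda total molecules per droplet and allele fraction theta.  The
caller integrates this droplet-level likelihood over the nuisance
parameters (lambda, f) for each fetal-genotype hypothesis and reports the
posterior probability that the fetus is heterozygous.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp, xlogy

from ._exceptions import (
    DegenerateInputError,
    InconsistentAssayError,
    InvalidInputError,
    SaturationError,
)

__all__ = [
    "DropletCounts",
    "ConcentrationEstimate",
    "FetalFractionEstimate",
    "Genotype",
    "GenotypePosterior",
    "GenotypeCall",
    "InferenceSettings",
    "poisson_concentration",
    "expected_variant_fraction",
    "fetal_fraction_from_xy",
    "fetal_fraction_from_xy_approx",
    "fetal_fraction_from_snp",
    "genotype_posterior",
    "call_genotype",
]

# Reporting thresholds: >= 0.95 posterior reports N/M, <= 0.05 reports N/N.
CALL_THRESHOLD_NM = 0.95
CALL_THRESHOLD_NN = 0.05


class Genotype(str, enum.Enum):
    """Fetal genotype hypothesis relative to the maternal heterozygous variant.

    NM: fetus inherited the maternal variant (heterozygous, affected).
    NN: fetus did not inherit the variant (homozygous wild type).
    """

    NM = "NM"
    NN = "NN"


@dataclass(frozen=True)
class DropletCounts:
    """Raw counts for one ddPCR target channel.

    Parameters
    ----------
    target_label : str
        Channel name, e.g. ``"variant"``, ``"ZFY"``.
    positives : int
        Droplets positive for the target.
    total : int
        Total accepted droplets.
    """

    target_label: str
    positives: int
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise InvalidInputError(
                f"{self.target_label}: total droplets must be positive, got {self.total}"
            )
        if not 0 <= self.positives <= self.total:
            raise InvalidInputError(
                f"{self.target_label}: positives ({self.positives}) must lie in "
                f"[0, {self.total}]"
            )

    @property
    def fraction(self) -> float:
        return self.positives / self.total


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Mean target molecules per droplet with a confidence interval."""

    lam: float
    ci_low: float
    ci_high: float
    n_droplets: int

    @property
    def sd(self) -> float:
        """Delta-method standard deviation of the concentration estimate."""
        p = -math.expm1(-self.lam)
        if p >= 1.0:
            return math.inf
        return math.sqrt(p / ((1.0 - p) * self.n_droplets))


@dataclass(frozen=True)
class FetalFractionEstimate:
    """Point estimate and uncertainty of the fetal cfDNA fraction.

    ``method`` records how it was measured: "XY" (ZFX/ZFY duplex for a male
    fetus) or "SNP" (paternally inherited fetus-specific allele).
    ``paternal_allele_droplets`` is the positive-droplet count of the
    fetus-specific channel, used by the QC rule requiring > 10 droplets.
    """

    f: float
    sd: float
    method: str
    paternal_allele_droplets: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise InvalidInputError(f"fetal fraction must be in [0, 1], got {self.f}")
        if self.sd < 0:
            raise InvalidInputError("fetal-fraction sd must be non-negative")
        if self.paternal_allele_droplets < 0:
            raise InvalidInputError("paternal allele droplet count must be >= 0")


@dataclass(frozen=True)
class GenotypePosterior:
    """Posterior over the two fetal-genotype hypotheses.

    ``p_het`` is P(fetus is N/M | droplet data); the log marginal
    likelihoods are reported per hypothesis so priors can be revisited.
    """

    p_het: float
    log_marginal_nm: float
    log_marginal_nn: float
    method: str
    converged: bool = True


@dataclass(frozen=True)
class GenotypeCall:
    """Clinical call from a posterior: NM / NN / inconclusive."""

    call: str
    p_het: float


@dataclass(frozen=True)
class InferenceSettings:
    """Settings for the genotype-posterior computation.

    Quadrature (default) integrates the likelihood on an adaptive
    (lambda, f) grid under a uniform lambda prior on
    [lambda_min, lambda_max] and the fetal-fraction assay likelihood
    (normal, truncated to (0, 0.5]) as the f prior.  The MCMC path runs a
    seeded Metropolis-within-Gibbs sampler over (genotype, lambda, f) and
    serves as a cross-check.
    """

    method: str = "quadrature"
    n_lambda: int = 401
    n_f: int = 201
    lambda_min: float = 1e-6
    lambda_max: float = 5.0
    f_max: float = 0.5
    # width of the adaptive grids, in posterior standard deviations
    grid_halfwidth_sd: float = 8.0
    mcmc_iterations: int = 3000
    mcmc_burn_in: int = 500
    mcmc_chains: int = 8
    seed: int = 0


def poisson_concentration(counts: DropletCounts, conf: float = 0.95) -> ConcentrationEstimate:
    """Estimate mean molecules per droplet from positive-droplet counts.

    Under Poisson loading the probability a droplet is positive is
    1 - exp(-lambda), so the maximum-likelihood concentration is
    lambda = -ln(1 - k/n).  The confidence interval is the exact
    Clopper-Pearson interval on the positive fraction mapped through the
    same transform.
    """
    if counts.positives == counts.total:
        raise SaturationError(
            f"{counts.target_label}: all {counts.total} droplets positive; "
            "concentration is not identifiable"
        )
    if not 0.0 < conf < 1.0:
        raise InvalidInputError(f"confidence level must be in (0, 1), got {conf}")
    k, n = counts.positives, counts.total
    lam = -math.log1p(-k / n)
    alpha = 1.0 - conf
    p_low = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    p_high = stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return ConcentrationEstimate(
        lam=lam,
        ci_low=-math.log1p(-p_low),
        ci_high=-math.log1p(-p_high),
        n_droplets=n,
    )


def expected_variant_fraction(h: Genotype | str, f: float) -> float:
    """Expected variant-allele fraction theta in maternal plasma cfDNA.

    The mother is heterozygous, so her cfDNA contributes variant fraction
    1/2 on (1 - f) of molecules.  An N/M fetus also contributes 1/2,
    leaving theta = 1/2 regardless of f; an N/N fetus contributes no
    variant alleles, so theta = (1 - f)/2.
    """
    if not 0.0 <= f <= 1.0:
        raise InvalidInputError(f"fetal fraction must be in [0, 1], got {f}")
    h = Genotype(h)
    if h is Genotype.NM:
        return 0.5
    return (1.0 - f) / 2.0


def _lambda_var(counts: DropletCounts) -> float:
    # delta-method variance of -ln(1 - k/n)
    p = counts.fraction
    return p / ((1.0 - p) * counts.total) if p < 1.0 else math.inf


def fetal_fraction_from_xy(
    zfy: DropletCounts, zfx: DropletCounts
) -> FetalFractionEstimate:
    """Fetal fraction from ZFX/ZFY concentrations (male fetus).

    Maternal genomes contribute two ZFX copies; each fetal genome one ZFX
    and one ZFY.  With r = lambda_ZFY / lambda_ZFX the exact inversion is
    f = 2 r / (1 + r); the standard deviation is propagated by the delta
    method from the per-channel binomial sampling variances.
    """
    lam_y = poisson_concentration(zfy).lam if zfy.positives < zfy.total else None
    if lam_y is None:
        raise SaturationError("ZFY channel saturated")
    lam_x = poisson_concentration(zfx).lam
    if lam_x == 0.0:
        raise InvalidInputError("ZFX concentration is zero; fetal fraction undefined")
    f = 2.0 * lam_y / (lam_x + lam_y)
    if f > 1.0:
        raise InconsistentAssayError(
            f"ZFY exceeds ZFX concentration (implied fetal fraction {f:.3f} > 1)"
        )
    s = lam_x + lam_y
    dfy = 2.0 * lam_x / s**2
    dfx = -2.0 * lam_y / s**2
    sd = math.sqrt(dfy**2 * _lambda_var(zfy) + dfx**2 * _lambda_var(zfx))
    return FetalFractionEstimate(
        f=f, sd=sd, method="XY", paternal_allele_droplets=zfy.positives
    )


def fetal_fraction_from_xy_approx(
    zfy: DropletCounts, zfx: DropletCounts
) -> FetalFractionEstimate:
    """Common approximation f ~= 2 * lambda_ZFY / lambda_ZFX.

    Provided for cross-checks only; overestimates f by a factor
    (1 + r)/1 relative to the exact inversion.  See
    :func:`fetal_fraction_from_xy` for the exact form used by the pipeline.
    """
    lam_y = poisson_concentration(zfy).lam
    lam_x = poisson_concentration(zfx).lam
    if lam_x == 0.0:
        raise InvalidInputError("ZFX concentration is zero; fetal fraction undefined")
    f = min(2.0 * lam_y / lam_x, 1.0)
    r = lam_y / lam_x
    dfy = 2.0 / lam_x
    dfx = -2.0 * lam_y / lam_x**2
    sd = math.sqrt(dfy**2 * _lambda_var(zfy) + dfx**2 * _lambda_var(zfx))
    return FetalFractionEstimate(
        f=f, sd=sd, method="XY", paternal_allele_droplets=zfy.positives
    )


def fetal_fraction_from_snp(
    paternal: DropletCounts, reference: DropletCounts
) -> FetalFractionEstimate:
    """Fetal fraction from an informative SNP (mother homozygous reference,
    paternal allele fetus-specific).

    Only half the fetal genome equivalents carry the paternal allele, so
    with p = lambda_pat / (lambda_pat + lambda_ref), f = 2p.
    """
    lam_p = poisson_concentration(paternal).lam
    lam_r = poisson_concentration(reference).lam
    tot = lam_p + lam_r
    if tot == 0.0:
        raise InvalidInputError("both SNP channels empty; fetal fraction undefined")
    f = 2.0 * lam_p / tot
    if f > 1.0:
        raise InconsistentAssayError(
            f"paternal allele exceeds reference concentration (implied f {f:.3f} > 1)"
        )
    dfp = 2.0 * lam_r / tot**2
    dfr = -2.0 * lam_p / tot**2
    sd = math.sqrt(dfp**2 * _lambda_var(paternal) + dfr**2 * _lambda_var(reference))
    return FetalFractionEstimate(
        f=f, sd=sd, method="SNP", paternal_allele_droplets=paternal.positives
    )


def _droplet_loglik(
    kv: int, nv: int, kw: int, nw: int, lam: np.ndarray, theta: np.ndarray
) -> np.ndarray:
    """Joint log likelihood of both channels on broadcastable (lam, theta).

    Includes the binomial coefficients so the result is a genuine log
    probability mass, comparable across hypotheses and methods.
    """
    p_v = -np.expm1(-lam * theta)
    p_w = -np.expm1(-lam * (1.0 - theta))
    ll = (
        xlogy(kv, p_v)
        + xlogy(nv - kv, 1.0 - p_v)
        + xlogy(kw, p_w)
        + xlogy(nw - kw, 1.0 - p_w)
    )
    const = (
        gammaln(nv + 1) - gammaln(kv + 1) - gammaln(nv - kv + 1)
        + gammaln(nw + 1) - gammaln(kw + 1) - gammaln(nw - kw + 1)
    )
    return ll + const


def _f_grid(ff: FetalFractionEstimate, settings: InferenceSettings) -> np.ndarray:
    """Quadrature nodes for the fetal fraction, spanning the assay likelihood
    truncated to (0, f_max]."""
    if ff.sd == 0.0:
        if ff.f > settings.f_max:
            raise DegenerateInputError(
                f"fetal fraction {ff.f} outside the supported range (0, {settings.f_max}]"
            )
        return np.array([ff.f])
    lo = max(1e-6, ff.f - settings.grid_halfwidth_sd * ff.sd)
    hi = min(settings.f_max, ff.f + settings.grid_halfwidth_sd * ff.sd)
    if hi <= 0.0 or hi <= lo:
        raise DegenerateInputError(
            "fetal-fraction likelihood has no support in (0, f_max]"
        )
    return np.linspace(lo, hi, settings.n_f)


def _lambda_grid(
    kv: int, nv: int, kw: int, nw: int, settings: InferenceSettings
) -> np.ndarray:
    """Quadrature nodes for total concentration, centred on the pooled MLE.

    The prior is uniform on [lambda_min, lambda_max]; the nodes cover the
    region where the likelihood has any mass (MLE +/- grid_halfwidth_sd
    standard deviations), clipped to the prior support.
    """
    lam_hat = 0.0
    var = 0.0
    for k, n in ((kv, nv), (kw, nw)):
        p = min(k / n, 1.0 - 1.0 / n)  # guard saturated channel
        lam_hat += -math.log1p(-p)
        var += p / ((1.0 - p) * n)
    sd = math.sqrt(var)
    if lam_hat <= 0.0:
        lo, hi = settings.lambda_min, min(settings.lambda_max, 20.0 / max(nv, nw))
    else:
        lo = max(settings.lambda_min, lam_hat - settings.grid_halfwidth_sd * sd)
        hi = min(settings.lambda_max, lam_hat + settings.grid_halfwidth_sd * sd)
    if hi <= lo:
        lo, hi = settings.lambda_min, settings.lambda_max
    return np.linspace(lo, hi, settings.n_lambda)


def _log_trapz_weights(x: np.ndarray) -> np.ndarray:
    if x.size == 1:
        return np.zeros(1)
    w = np.empty_like(x)
    w[0] = (x[1] - x[0]) / 2.0
    w[-1] = (x[-1] - x[-2]) / 2.0
    w[1:-1] = (x[2:] - x[:-2]) / 2.0
    return np.log(w)


def _log_f_prior(fs: np.ndarray, ff: FetalFractionEstimate, f_max: float) -> np.ndarray:
    if ff.sd == 0.0:
        return np.zeros(1)
    lp = stats.norm.logpdf(fs, loc=ff.f, scale=ff.sd)
    # normalise over the truncation interval (0, f_max]
    mass = stats.norm.cdf(f_max, ff.f, ff.sd) - stats.norm.cdf(0.0, ff.f, ff.sd)
    if mass <= 0.0:
        raise DegenerateInputError("fetal-fraction likelihood has no mass in (0, f_max]")
    return lp - math.log(mass)


def _quadrature_log_marginals(
    kv: int,
    nv: int,
    kw: int,
    nw: int,
    ff: FetalFractionEstimate,
    settings: InferenceSettings,
) -> tuple[float, float]:
    lam = _lambda_grid(kv, nv, kw, nw, settings)[:, None]
    fs = _f_grid(ff, settings)[None, :]
    log_wf = _log_f_prior(fs[0], ff, settings.f_max) + _log_trapz_weights(fs[0])
    log_wl = _log_trapz_weights(lam[:, 0]) - math.log(
        settings.lambda_max - settings.lambda_min
    )
    out = []
    for h in (Genotype.NM, Genotype.NN):
        if h is Genotype.NM:
            theta = np.full_like(fs, 0.5)
        else:
            theta = (1.0 - fs) / 2.0
        ll = _droplet_loglik(kv, nv, kw, nw, lam, theta)
        out.append(float(logsumexp(ll + log_wf[None, :] + log_wl[:, None])))
    return out[0], out[1]


def _mcmc_p_het(
    kv: int,
    nv: int,
    kw: int,
    nw: int,
    ff: FetalFractionEstimate,
    prior_nm: float,
    settings: InferenceSettings,
) -> tuple[float, bool]:
    """Metropolis-within-Gibbs over (genotype, lambda, f), vectorised over
    chains.  The genotype indicator is updated by an exact Gibbs draw from
    its full conditional; lambda and f by random-walk Metropolis steps."""
    rng = np.random.default_rng(settings.seed)
    n_chains = settings.mcmc_chains
    lam_hat = -math.log1p(-min(kv / nv, 1 - 1 / nv)) - math.log1p(-min(kw / nw, 1 - 1 / nw))
    lam_hat = max(lam_hat, 10.0 / max(nv, nw))
    lam_scale = max(lam_hat / math.sqrt(max(kv + kw, 4)), 1e-5) * 2.0
    f0 = min(max(ff.f, 1e-3), settings.f_max)
    f_scale = max(ff.sd, 1e-4) * 2.0

    lam = lam_hat * np.exp(rng.normal(0.0, 0.05, n_chains))
    f = np.clip(f0 + rng.normal(0.0, max(ff.sd, 1e-4), n_chains), 1e-4, settings.f_max)
    log_prior_ratio = math.log(prior_nm) - math.log1p(-prior_nm)

    def ll(lam_a: np.ndarray, f_a: np.ndarray, nm: bool) -> np.ndarray:
        theta = np.full_like(f_a, 0.5) if nm else (1.0 - f_a) / 2.0
        return _droplet_loglik(kv, nv, kw, nw, lam_a, theta)

    def log_f_prior(f_a: np.ndarray) -> np.ndarray:
        if ff.sd == 0.0:
            return np.zeros_like(f_a)
        return stats.norm.logpdf(f_a, ff.f, ff.sd)

    h = rng.random(n_chains) < prior_nm
    het_draws = np.zeros(n_chains)
    n_kept = 0
    kept_per_chain = []
    for it in range(settings.mcmc_iterations):
        # Gibbs update of the genotype indicator
        delta = ll(lam, f, True) - ll(lam, f, False) + log_prior_ratio
        p_nm = 1.0 / (1.0 + np.exp(-delta))
        h = rng.random(n_chains) < p_nm

        cur = np.where(h, ll(lam, f, True), ll(lam, f, False))

        # Metropolis step on lambda
        lam_prop = lam + rng.normal(0.0, lam_scale, n_chains)
        ok = (lam_prop > settings.lambda_min) & (lam_prop < settings.lambda_max)
        lp = np.where(ok, np.where(h, ll(lam_prop, f, True), ll(lam_prop, f, False)), -np.inf)
        accept = np.log(rng.random(n_chains)) < lp - cur
        lam = np.where(accept, lam_prop, lam)
        cur = np.where(accept, lp, cur)

        # Metropolis step on f (skipped when the assay pins f exactly)
        if ff.sd > 0.0:
            f_prop = f + rng.normal(0.0, f_scale, n_chains)
            ok = (f_prop > 0.0) & (f_prop <= settings.f_max)
            lp = np.where(
                ok,
                np.where(h, ll(lam, f_prop, True), ll(lam, f_prop, False))
                + log_f_prior(f_prop),
                -np.inf,
            )
            accept = np.log(rng.random(n_chains)) < lp - (cur + log_f_prior(f))
            f = np.where(accept, f_prop, f)

        if it >= settings.mcmc_burn_in:
            # use the Rao-Blackwellised P(h = NM | lam, f) rather than the
            # binary draw: much lower Monte Carlo variance
            het_draws += p_nm
            n_kept += 1
            kept_per_chain.append(p_nm)

    per_chain = np.mean(np.asarray(kept_per_chain), axis=0)
    p_het = float(het_draws.sum() / (n_kept * n_chains))
    converged = bool(np.ptp(per_chain) < 0.05 or np.std(per_chain) < 0.02)
    return p_het, converged


def genotype_posterior(
    variant: DropletCounts,
    wildtype: DropletCounts,
    ff: FetalFractionEstimate,
    prior_nm: float = 0.5,
    settings: InferenceSettings | None = None,
) -> GenotypePosterior:
    """Posterior probability that the fetus inherited the maternal variant.

    For each hypothesis h in {NM, NN} the marginal likelihood integrates
    the droplet-level binomial likelihood

        k_v ~ Binomial(n_v, 1 - exp(-lambda * theta(h, f)))
        k_w ~ Binomial(n_w, 1 - exp(-lambda * (1 - theta(h, f))))

    over lambda (uniform prior) and f (fetal-fraction assay likelihood,
    truncated normal on (0, 0.5]).  ``p_het`` combines the marginals with
    ``prior_nm`` (default 0.5, the Mendelian expectation for a
    heterozygous x wild-type cross).

    The default method is deterministic quadrature; ``settings.method =
    "mcmc"`` runs a seeded sampler instead (used as a cross-check).
    """
    if settings is None:
        settings = InferenceSettings()
    if not 0.0 < prior_nm < 1.0:
        raise InvalidInputError(f"prior_nm must be in (0, 1), got {prior_nm}")
    kv, nv = variant.positives, variant.total
    kw, nw = wildtype.positives, wildtype.total

    log_m_nm, log_m_nn = _quadrature_log_marginals(kv, nv, kw, nw, ff, settings)
    if settings.method == "quadrature":
        a = log_m_nm + math.log(prior_nm)
        b = log_m_nn + math.log1p(-prior_nm)
        p_het = float(np.exp(a - np.logaddexp(a, b)))
        return GenotypePosterior(
            p_het=p_het,
            log_marginal_nm=log_m_nm,
            log_marginal_nn=log_m_nn,
            method="quadrature",
        )
    if settings.method == "mcmc":
        p_het, converged = _mcmc_p_het(kv, nv, kw, nw, ff, prior_nm, settings)
        return GenotypePosterior(
            p_het=p_het,
            log_marginal_nm=log_m_nm,
            log_marginal_nn=log_m_nn,
            method="mcmc",
            converged=converged,
        )
    raise InvalidInputError(f"unknown inference method {settings.method!r}")


def call_genotype(post: GenotypePosterior) -> GenotypeCall:
    """Apply the reporting thresholds to a posterior.

    N/M is reported when p_het >= 0.95, N/N when p_het <= 0.05 (both
    inclusive); anything between is inconclusive and triggers a
    repeat-sample request downstream.  A non-converged posterior is never
    called.
    """
    if not post.converged:
        return GenotypeCall(call="inconclusive", p_het=post.p_het)
    if post.p_het >= CALL_THRESHOLD_NM:
        return GenotypeCall(call="NM", p_het=post.p_het)
    if post.p_het <= CALL_THRESHOLD_NN:
        return GenotypeCall(call="NN", p_het=post.p_het)
    return GenotypeCall(call="inconclusive", p_het=post.p_het)
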