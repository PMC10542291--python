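"""Synthetic study cohorts: ddPCR droplet data, fetal fractions, ultrasound
scans, confirmed genotypes and lab-workflow timings.

The generator is the forward model of the whole analysis: fetal genotype is
Bernoulli(1/2) (Mendelian cross of a heterozygous mother), fetal fraction
grows linearly with gestational age with lognormal noise, droplet counts
follow independent Poisson loading per channel, and abdominal-circumference
percentiles are drawn from genotype-conditional Gaussian z-score models
calibrated to the published 75th/90th-percentile exceedance proportions.
The confirmed genotype equals the latent truth by default (perfect
reference standard).
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import GckNiptError, InvalidInputError
from .ddpcr import (
    DropletCounts,
    call_genotype,
    expected_variant_fraction,
    fetal_fraction_from_snp,
    genotype_posterior,
)
from .growth import GrowthStandard, ac_from_percentile

__all__ = [
    "AcModel",
    "calibrate_ac_model",
    "WorkflowModel",
    "FetalFractionModel",
    "CohortParams",
    "SyntheticCohort",
    "generate_ddpcr_counts",
    "generate_growth_standard",
    "generate_cohort",
]

# Published genotype-conditional classification proportions used to
# calibrate the AC percentile model: P(percentile < 75 | genotype) and
# P(percentile < 90 | genotype) for N/M (8/15, 13/15) and N/N (9/23, 12/23).
DEFAULT_AC_CALIBRATION = {
    "NM": (8 / 15, 13 / 15),
    "NN": (9 / 23, 12 / 23),
}


@dataclass(frozen=True)
class AcModel:
    """Genotype-conditional z-score distributions of the AC measurement.

    An individual's AC percentile is 100 * Phi(z) with z ~ Normal(mu_g,
    sigma_g) for genotype g.  sigma = 0 collapses to a point mass (used
    for degenerate test scenarios).
    """

    mu_nm: float
    sigma_nm: float
    mu_nn: float
    sigma_nn: float

    def draw_percentile(self, genotype: str, rng: np.random.Generator) -> float:
        mu, sigma = (
            (self.mu_nm, self.sigma_nm) if genotype == "NM" else (self.mu_nn, self.sigma_nn)
        )
        z = mu if sigma == 0.0 else rng.normal(mu, sigma)
        return float(100.0 * stats.norm.cdf(z))


def calibrate_ac_model(
    proportions: dict[str, tuple[float, float]] | None = None,
) -> AcModel:
    """Solve the per-genotype Normal z-score parameters from the two
    classification proportions P(pct < 75 | g) and P(pct < 90 | g).

    With q_t = Phi^-1(t/100), the constraints (q_75 - mu)/sigma =
    Phi^-1(p75) and (q_90 - mu)/sigma = Phi^-1(p90) have the closed-form
    solution sigma = (q_90 - q_75)/(Phi^-1(p90) - Phi^-1(p75)).
    """
    props = proportions or DEFAULT_AC_CALIBRATION
    q75, q90 = stats.norm.ppf(0.75), stats.norm.ppf(0.90)
    params: dict[str, tuple[float, float]] = {}
    for g, (p75, p90) in props.items():
        if not 0.0 < p75 < p90 < 1.0:
            raise InvalidInputError(
                f"calibration proportions for {g} must satisfy 0 < p75 < p90 < 1"
            )
        a75, a90 = stats.norm.ppf(p75), stats.norm.ppf(p90)
        sigma = (q90 - q75) / (a90 - a75)
        mu = q75 - a75 * sigma
        params[g] = (mu, sigma)
    return AcModel(
        mu_nm=params["NM"][0],
        sigma_nm=params["NM"][1],
        mu_nn=params["NN"][0],
        sigma_nn=params["NN"][1],
    )


@dataclass(frozen=True)
class FetalFractionModel:
    """Fetal fraction vs gestational age: f = (base + slope*(ga - 10)) *
    LogNormal(0, noise_sd), truncated to (floor, cap)."""

    base_at_10wk: float = 0.03
    slope_per_week: float = 0.005
    noise_sd: float = 0.20
    floor: float = 0.002
    cap: float = 0.40

    def draw(self, ga: float, rng: np.random.Generator) -> float:
        mean = self.base_at_10wk + self.slope_per_week * (ga - 10.0)
        f = mean * math.exp(rng.normal(0.0, self.noise_sd))
        return float(min(max(f, self.floor), self.cap))


@dataclass(frozen=True)
class WorkflowModel:
    """Lab turnaround components, in weeks, and cohort-flow probabilities."""

    p_assay_available: float = 42 / 43
    p_assay_preexisting: float = 0.24
    design_weeks_range: tuple[float, float] = (2.0, 8.0)
    processing_weeks_range: tuple[float, float] = (1.0, 3.0)
    repeat_delay_weeks: float = 6.0
    p_repeat_received: float = 0.9


@dataclass(frozen=True)
class CohortParams:
    """Study conditions for a synthetic cohort.  ``seed`` is mandatory."""

    n_pregnancies: int
    seed: int
    p_fetus_nm: float = 0.5
    droplets_per_channel: int = 20_000
    lambda_total: float = 0.2
    lambda_ff_assay: float = 0.2
    ga_first_sample_range: tuple[float, float] = (8.0, 32.0)
    ff_model: FetalFractionModel = field(default_factory=FetalFractionModel)
    ac_model: AcModel | None = None  # None -> calibrate_ac_model() defaults
    workflow: WorkflowModel = field(default_factory=WorkflowModel)
    p_second_scan: float = 5 / 38
    p_reference_error: float = 0.0
    start_date: dt.date = dt.date(2024, 1, 1)

    def __post_init__(self) -> None:
        for name in ("p_fetus_nm", "p_second_scan", "p_reference_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name} must be in [0, 1], got {v}")
        if self.n_pregnancies <= 0 or self.droplets_per_channel <= 0:
            raise InvalidInputError("counts must be positive")
        if self.lambda_total <= 0:
            raise InvalidInputError("lambda_total must be positive")


@dataclass
class SyntheticCohort:
    """Generated cohort tables plus the latent truth (never read by the
    analysis pipeline; evaluation only)."""

    samples: pd.DataFrame
    scans: pd.DataFrame
    confirmed: pd.DataFrame
    truth: pd.DataFrame
    growth_standard: GrowthStandard
    ac_model: AcModel
    params: CohortParams

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.samples.to_csv(out / "samples.csv", index=False)
        self.scans.to_csv(out / "scans.csv", index=False)
        self.confirmed.to_csv(out / "confirmed.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)
        self.growth_standard.to_json(out / "growth_standard.json")
        (out / "calibration.json").write_text(
            json.dumps(asdict(self.ac_model), indent=2) + "\n"
        )


def generate_ddpcr_counts(
    theta: float,
    lambda_total: float,
    n_droplets: int,
    seed: int | np.random.Generator,
) -> tuple[DropletCounts, DropletCounts]:
    """Forward-simulate one duplex ddPCR well.

    Each channel is an independent Poisson loading: the variant channel is
    positive with probability 1 - exp(-lambda*theta), the wild-type
    channel with 1 - exp(-lambda*(1 - theta)).
    """
    if not 0.0 <= theta <= 1.0:
        raise InvalidInputError(f"theta must be in [0, 1], got {theta}")
    if lambda_total <= 0.0:
        raise InvalidInputError("lambda_total must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_v = -math.expm1(-lambda_total * theta)
    p_w = -math.expm1(-lambda_total * (1.0 - theta))
    kv = int(rng.binomial(n_droplets, p_v))
    kw = int(rng.binomial(n_droplets, p_w))
    return (
        DropletCounts("variant", kv, n_droplets),
        DropletCounts("wildtype", kw, n_droplets),
    )


def generate_growth_standard(
    base_mm: float = 50.0,
    slope_mm_per_week: float = 8.0,
    sd_fraction: float = 0.07,
    ga_range: tuple[float, float] = (14.0, 42.0),
) -> GrowthStandard:
    """Synthetic linear growth standard: mean = base + slope*ga, SD
    proportional to the mean."""
    if slope_mm_per_week <= 0 or sd_fraction <= 0:
        raise InvalidInputError("slope and SD fraction must be positive")
    return GrowthStandard(
        name="synthetic-linear-v1",
        mean_coeffs=(base_mm, slope_mm_per_week),
        sd_coeffs=(sd_fraction * base_mm, sd_fraction * slope_mm_per_week),
        ga_range=ga_range,
    )


def _ff_channels(
    f: float, lam_assay: float, n: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Fetus-specific (ch1) and reference (ch2) fetal-fraction assay counts.

    Half the fetal genome equivalents carry the fetus-specific allele
    (ZFY, or the paternal SNP allele), so lambda_ch1 = lam*f/2 and
    lambda_ch2 = lam*(1 - f/2)."""
    p1 = -math.expm1(-lam_assay * f / 2.0)
    p2 = -math.expm1(-lam_assay * (1.0 - f / 2.0))
    return int(rng.binomial(n, p1)), int(rng.binomial(n, p2))


def generate_cohort(params: CohortParams) -> SyntheticCohort:
    """Generate a complete synthetic cohort under ``params``.

    Per pregnancy: a latent genotype, a gestational-age-dependent fetal
    fraction, duplex variant/wild-type droplet counts at theta =
    expected_variant_fraction(genotype, f), a consistent fetal-fraction
    assay, one or two ultrasound scans in the 26-30-week window, workflow
    dates, and a confirmed genotype.  Mirroring the laboratory workflow,
    a first sample that is not reportable (QC failure or an inconclusive
    posterior, as determined by actually running the caller on the
    generated counts) triggers a repeat sample six weeks later with
    probability ``workflow.p_repeat_received``; the report date is set
    only on reportable samples.
    """
    rng = np.random.default_rng(params.seed)
    ac_model = params.ac_model or calibrate_ac_model()
    std = generate_growth_standard()
    wf = params.workflow

    sample_rows, scan_rows, confirmed_rows, truth_rows = [], [], [], []
    for i in range(params.n_pregnancies):
        pid = f"P{i + 1:04d}"
        genotype = "NM" if rng.random() < params.p_fetus_nm else "NN"
        assay_available = rng.random() < wf.p_assay_available
        assay_preexisting = assay_available and (rng.random() < wf.p_assay_preexisting)
        ga1 = float(rng.uniform(*params.ga_first_sample_range))
        date1 = params.start_date + dt.timedelta(days=int(rng.integers(0, 365)))
        design_weeks = 0.0 if assay_preexisting else float(rng.uniform(*wf.design_weeks_range))

        def emit_sample(sample_no: int, ga: float, date_received: dt.date,
                        extra_delay_weeks: float) -> bool:
            """Append one sample row; returns True if it is reportable."""
            f = params.ff_model.draw(ga, rng)
            ch1, ch2 = _ff_channels(
                f, params.lambda_ff_assay, params.droplets_per_channel, rng
            )
            theta = expected_variant_fraction(genotype, f)
            var, wt = generate_ddpcr_counts(
                theta, params.lambda_total, params.droplets_per_channel, rng
            )
            # the lab's reportability decision: QC gates plus a conclusive
            # call, evaluated by running the caller on the generated counts
            qc_ok = False
            if assay_available:
                try:
                    ff_hat = fetal_fraction_from_snp(
                        DropletCounts("ff_ch1", ch1, params.droplets_per_channel),
                        DropletCounts("ff_ch2", ch2, params.droplets_per_channel),
                    )
                    if ff_hat.f > 0.02 and ch1 > 10:
                        post = genotype_posterior(var, wt, ff_hat)
                        qc_ok = call_genotype(post).call != "inconclusive"
                except GckNiptError:
                    qc_ok = False
            processing = float(rng.uniform(*wf.processing_weeks_range))
            date_reported = (
                date_received + dt.timedelta(days=round(7 * (extra_delay_weeks + processing)))
                if qc_ok
                else None
            )
            sample_rows.append(
                {
                    "pregnancy_id": pid,
                    "sample_id": f"{pid}-S{sample_no}",
                    "date_received": date_received.isoformat(),
                    "ga_weeks": round(ga, 2),
                    "assay_available": assay_available,
                    "assay_specific": True,
                    "assay_preexisting": assay_preexisting,
                    "var_pos": var.positives if assay_available else 0,
                    "var_tot": var.total,
                    "wt_pos": wt.positives if assay_available else 0,
                    "wt_tot": wt.total,
                    "ff_method": "XY" if rng.random() < 0.5 else "SNP",
                    "ff_ch1_pos": ch1,
                    "ff_ch1_tot": params.droplets_per_channel,
                    "ff_ch2_pos": ch2,
                    "ff_ch2_tot": params.droplets_per_channel,
                    "date_reported": date_reported.isoformat() if date_reported else "",
                }
            )
            truth_rows.append(
                {
                    "pregnancy_id": pid,
                    "sample_id": f"{pid}-S{sample_no}",
                    "genotype": genotype,
                    "fetal_fraction": f,
                    "theta": theta,
                }
            )
            return qc_ok

        first_ok = emit_sample(1, ga1, date1, design_weeks)
        if assay_available and not first_ok and rng.random() < wf.p_repeat_received:
            ga2 = ga1 + wf.repeat_delay_weeks
            if ga2 < 42.0:
                date2 = date1 + dt.timedelta(days=round(7 * wf.repeat_delay_weeks))
                emit_sample(2, ga2, date2, 0.0)

        n_scans = 1 + (1 if rng.random() < params.p_second_scan else 0)
        for _ in range(n_scans):
            ga_scan = float(rng.uniform(26.0, 30.0))
            pct = min(max(ac_model.draw_percentile(genotype, rng), 0.01), 99.99)
            scan_rows.append(
                {
                    "pregnancy_id": pid,
                    "ga_weeks": round(ga_scan, 2),
                    "ac_mm": round(ac_from_percentile(pct, ga_scan, std), 1),
                }
            )

        confirmed_g = genotype
        if params.p_reference_error > 0 and rng.random() < params.p_reference_error:
            confirmed_g = "NN" if genotype == "NM" else "NM"
        confirmed_rows.append({"pregnancy_id": pid, "genotype": confirmed_g})

    return SyntheticCohort(
        samples=pd.DataFrame(sample_rows),
        scans=pd.DataFrame(scan_rows),
        confirmed=pd.DataFrame(confirmed_rows),
        truth=pd.DataFrame(truth_rows),
        growth_standard=std,
        ac_model=ac_model,
        params=params,
    )
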