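"""Synthetic twin cohorts with the statistical structure the analysis assumes.

The generator draws, for each twin pair, latent additive-genetic (A),
common-environment (C) and unique-environment (E) components on the
arcsine-square-root scale: MZ co-twins receive an identical A draw, DZ
co-twins a bivariate A draw with correlation 1/2, C is shared within
pair, and E is independent per member.  The latent phenotype
``y = mu + A + C + E`` is clamped to [0, pi/2] and mapped through
``sin(y)**2`` to a focal-taxon proportion.  The remaining compositional
mass is split between sparse nuisance taxa (each present in a random
subset of samples) and an unassigned-read remainder, and read counts
are drawn multinomially at an overdispersed per-sample depth, so that
the read-depth screen, the prevalence filter and the pair-assembly step
are all exercised on realistic inputs.

A companion harness repeatedly generates cohorts, runs the full
pipeline and summarizes estimator bias, RMSE, confidence-interval
coverage and test rejection rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd

from .io_cohort import ParticipantRecord, TaxaCountTable
from .transforms import HALF_PI, inv_asin_sqrt

__all__ = ["SyntheticCohortSpec", "generate_cohort", "recovery_harness", "write_truth"]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of the data-generating model.

    Defaults mirror a single-ancestry stratum of a twin cohort of the
    size used in vaginal-microbiome twin work (84 MZ + 38 DZ pairs) with
    a focal taxon of heritability 0.347 on a total transformed-scale
    variance of 0.08 — small relative to the [0, pi/2] range so that
    boundary clamping is rare (< 1% of draws).
    """

    n_mz: int = 84
    n_dz: int = 38
    a2: float = 0.347 * 0.08
    c2: float = 0.0
    e2: float = 0.653 * 0.08
    mu: float = math.pi / 4.0
    n_noise_taxa: int = 20
    sparsity: float = 0.2
    mean_depth: float = 20000.0
    depth_dispersion: float = 4.0
    singleton_fraction: float = 0.05
    ancestry: str = "European"
    focal_taxon: str = "Lactobacillus_crispatus"
    seed: int = 0

    def __post_init__(self):
        if self.a2 < 0 or self.c2 < 0:
            raise ValueError("a2 and c2 must be nonnegative")
        if self.e2 <= 0:
            raise ValueError("e2 must be positive")
        if self.n_mz < 0 or self.n_dz < 0:
            raise ValueError("pair counts must be nonnegative")
        if not 0.0 < self.sparsity <= 1.0:
            raise ValueError("sparsity must be in (0, 1]")
        if not 0.0 <= self.singleton_fraction < 1.0:
            raise ValueError("singleton_fraction must be in [0, 1)")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")

    def h2(self) -> float:
        return self.a2 / (self.a2 + self.c2 + self.e2)


def _latent_phenotypes(spec: SyntheticCohortSpec, rng: np.random.Generator) -> tuple:
    """(y_mz, y_dz) latent pair phenotypes before clamping, shape (n, 2)."""
    sa, sc, se = math.sqrt(spec.a2), math.sqrt(spec.c2), math.sqrt(spec.e2)

    a_mz = sa * rng.standard_normal(spec.n_mz)[:, None] * np.ones((1, 2))
    # DZ additive values correlate 1/2: half-shared, half-segregating
    shared = rng.standard_normal(spec.n_dz)[:, None]
    own = rng.standard_normal((spec.n_dz, 2))
    a_dz = sa * (shared + own) / math.sqrt(2.0)

    c_mz = sc * rng.standard_normal(spec.n_mz)[:, None] * np.ones((1, 2))
    c_dz = sc * rng.standard_normal(spec.n_dz)[:, None] * np.ones((1, 2))
    e_mz = se * rng.standard_normal((spec.n_mz, 2))
    e_dz = se * rng.standard_normal((spec.n_dz, 2))

    return spec.mu + a_mz + c_mz + e_mz, spec.mu + a_dz + c_dz + e_dz


def generate_cohort(spec: SyntheticCohortSpec) -> tuple:
    """Generate ``(TaxaCountTable, participant records, truth)``.

    Fully reproducible from ``spec.seed``.  The truth record carries the
    generating parameters and realized latent summaries for use by
    recovery studies.
    """
    rng = np.random.default_rng(spec.seed)
    y_mz, y_dz = _latent_phenotypes(spec, rng)
    y = np.concatenate([y_mz, y_dz], axis=0)  # (n_pairs, 2)
    n_pairs = y.shape[0]
    zygosities = ["MZ"] * spec.n_mz + ["DZ"] * spec.n_dz

    clamped = np.clip(y, 0.0, HALF_PI)
    clamp_fraction = float(np.mean(clamped != y))
    p_focal = inv_asin_sqrt(clamped).reshape(-1)  # sample-major: pair by pair
    n_samples = p_focal.size

    # nuisance taxa: sparse presence, Dirichlet split of part of the
    # non-focal mass; the rest of each sample's reads stay unassigned
    k = spec.n_noise_taxa
    present = rng.random((n_samples, k)) < spec.sparsity
    weights = rng.gamma(0.5, size=(n_samples, k)) * present
    # unassigned pseudo-component keeps assigned reads strictly below depth
    unassigned_w = rng.gamma(2.0, size=n_samples)
    denom = weights.sum(axis=1) + unassigned_w
    noise_frac = weights / denom[:, None]
    p_noise = (1.0 - p_focal)[:, None] * noise_frac

    depth = _overdispersed_depth(spec, rng, n_samples)
    probs = np.concatenate(
        [p_focal[:, None], p_noise, (1.0 - p_focal - p_noise.sum(axis=1))[:, None]],
        axis=1,
    )
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum(axis=1, keepdims=True)
    counts_full = rng.multinomial(depth, probs)
    counts = counts_full[:, :-1]  # drop the unassigned remainder

    taxon_names = (spec.focal_taxon,) + tuple(f"noise_taxon_{j:03d}" for j in range(k))

    prefix = spec.ancestry[:3].upper()
    records = []
    sample_ids = []
    ages = np.round(np.clip(rng.normal(39.0, 13.0, n_pairs), 18.0, 78.0), 1)
    for ip in range(n_pairs):
        for member in ("A", "B"):
            pid = f"{prefix}{ip:04d}{member}"
            sample_ids.append(pid)
            records.append(
                ParticipantRecord(
                    participant_id=pid,
                    pair_id=f"{prefix}P{ip:04d}",
                    zygosity=zygosities[ip],
                    ancestry=spec.ancestry,
                    age=float(ages[ip]),
                    covariates=_draw_covariates(rng),
                )
            )

    # drop one member's sample from a fraction of pairs -> singletons
    n_single = int(round(spec.singleton_fraction * n_pairs))
    dropped = set()
    if n_single:
        pair_idx = rng.choice(n_pairs, size=n_single, replace=False)
        member_idx = rng.integers(0, 2, size=n_single)
        dropped = {2 * int(p) + int(m) for p, m in zip(pair_idx, member_idx)}
    keep = [i for i in range(n_samples) if i not in dropped]

    table = TaxaCountTable(
        sample_ids=tuple(sample_ids[i] for i in keep),
        taxon_names=taxon_names,
        counts=counts[keep],
        total_reads=depth[keep],
    )
    truth = dict(asdict(spec))
    truth["h2"] = spec.h2()
    truth["clamp_fraction"] = clamp_fraction
    truth["n_samples_emitted"] = len(keep)
    truth["n_singleton_pairs"] = n_single
    return table, records, truth


def _overdispersed_depth(spec, rng, n_samples) -> np.ndarray:
    """Negative-binomial read depths (gamma-Poisson mixture)."""
    r = spec.depth_dispersion
    lam = rng.gamma(shape=r, scale=spec.mean_depth / r, size=n_samples)
    return rng.poisson(lam).astype(np.int64)


def _draw_covariates(rng: np.random.Generator) -> dict:
    covs = {}
    if rng.random() > 0.12:
        covs["bmi"] = float(np.round(np.clip(rng.normal(28.0, 6.5), 17.0, 50.0), 2))
    if rng.random() > 0.02:
        covs["ph"] = float(np.round(np.clip(rng.normal(5.0, 1.1), 4.0, 7.0), 1))
    if rng.random() > 0.03:
        covs["bacterial_vaginosis"] = "yes" if rng.random() < 0.11 else "no"
    if rng.random() > 0.12:
        covs["current_smoking"] = "yes" if rng.random() < 0.28 else "no"
    return covs


def write_truth(truth: dict, path) -> None:
    """Write the generating truth as a key=value sidecar file."""
    with open(path, "w") as fh:
        for key, value in truth.items():
            fh.write(f"{key}={value}\n")


def recovery_harness(
    spec: SyntheticCohortSpec,
    replicates: int,
    min_reads: int = 5000,
    alpha: float = 0.05,
    compute_ci: bool = False,
) -> dict:
    """Estimator calibration study: generate, analyze, summarize.

    Each replicate generates a cohort from ``spec`` (with a distinct
    per-replicate seed derived from ``spec.seed``), runs the full
    pipeline (depth screen, proportions, pair assembly, transform) and
    the heritability test, and records the AE-model estimates.  Returns
    a summary with per-replicate results, bias and RMSE of the
    standardized heritability estimate, the rejection rate of the
    AE-vs-E likelihood-ratio test at ``alpha``, and (optionally) the
    empirical coverage of the 95% profile-likelihood interval for the
    additive-genetic variance.
    """
    from .pipeline import paired_phenotypes_from_table
    from . import twin_model

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    for rep in range(replicates):
        rep_seed = (spec.seed * 1000003 + 7919 * rep + 1) % (2**31)
        rep_spec = replace(spec, seed=rep_seed)
        table, records, truth = generate_cohort(rep_spec)
        data = paired_phenotypes_from_table(
            table, records, spec.focal_taxon, min_reads=min_reads
        )
        h2, p, fits = twin_model.heritability_test(data)
        row = {
            "replicate": rep,
            "h2_hat": h2,
            "a2_hat": fits["AE"].components.a2,
            "e2_hat": fits["AE"].components.e2,
            "p_value": p,
            "reject": p < alpha,
            "n_mz": data.n_mz,
            "n_dz": data.n_dz,
        }
        if compute_ci:
            ci = twin_model.confidence_intervals(fits["AE"], data)
            lo, hi = ci["A"]
            row["a2_ci_low"], row["a2_ci_high"] = lo, hi
            row["a2_covered"] = bool(lo <= spec.a2 <= hi)
        rows.append(row)
    df = pd.DataFrame(rows)
    h2_true = spec.h2()
    summary = {
        "replicates": replicates,
        "h2_true": h2_true,
        "h2_mean": float(df["h2_hat"].mean()),
        "h2_bias": float(df["h2_hat"].mean() - h2_true),
        "h2_rmse": float(np.sqrt(np.mean((df["h2_hat"] - h2_true) ** 2))),
        "rejection_rate": float(df["reject"].mean()),
        "results": df,
    }
    if compute_ci:
        summary["ci_coverage"] = float(df["a2_covered"].mean())
    return summary
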