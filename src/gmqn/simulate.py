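"""Synthetic two-channel methylation-array data with known ground truth.

The generator is phenomenological, not a scanner-physics model.  Each probe
gets a true methylation fraction beta drawn from a three-component beta
mixture (the bimodal human methylome: most sites near 0 or 1, a minority
intermediate) and a total intensity T drawn once per probe from a
log-normal (probe chemistry is consistent across arrays).  A measurement is

    M = beta * T + noise,   U = (1 - beta) * T + noise

with additive Gaussian background noise floored at 0.  For sites with
extreme beta one of the two signals is near zero — exactly the "dark"
population that makes the pooled per-channel Infinium I intensities
decompose into a low-mean and a broad high-mean Gaussian.  Infinium II
probes additionally compress beta toward 0.5 by a monotone distortion
before intensities are formed (the probe-design bias), and each batch
applies its own affine scale/shift per channel — the distortion class the
between-array step removes.

Designated probes may carry case/control effects, a linear covariate
relationship (e.g. age), or be paired with a genomically adjacent probe
sharing the same true beta.  Everything is driven by one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_signals import SignalSample

__all__ = [
    "BatchEffect",
    "SimulationConfig",
    "GroundTruth",
    "simulate_dataset",
    "simulate_replicates",
    "random_batch_effects",
]

IDENTITY_BATCH = None  # set below


@dataclass(frozen=True)
class BatchEffect:
    """Affine per-channel intensity distortion of one batch."""

    scale_red: float = 1.0
    shift_red: float = 0.0
    scale_green: float = 1.0
    shift_green: float = 0.0
    scale_type2: float = 1.0
    shift_type2: float = 0.0

    def __post_init__(self):
        for name in ("scale_red", "scale_green", "scale_type2"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


IDENTITY_BATCH = BatchEffect()


def random_batch_effects(
    n: int,
    rng: np.random.Generator,
    scale_range: tuple[float, float] = (0.7, 1.4),
    shift_range: tuple[float, float] = (50.0, 400.0),
) -> tuple[BatchEffect, ...]:
    """Batch 0 is the identity; later batches get random affine distortions."""
    effects = [IDENTITY_BATCH]
    for _ in range(1, n):
        effects.append(
            BatchEffect(
                scale_red=float(rng.uniform(*scale_range)),
                shift_red=float(rng.uniform(*shift_range)),
                scale_green=float(rng.uniform(*scale_range)),
                shift_green=float(rng.uniform(*shift_range)),
                scale_type2=float(rng.uniform(*scale_range)),
                shift_type2=float(rng.uniform(*shift_range)),
            )
        )
    return tuple(effects)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults give a desk-scale array: 2,400 Infinium I probes split evenly
    between channels, 2,400 Infinium II probes, a 0.4/0.2/0.4
    hypo/mid/hyper beta mixture, probe intensities around 6,000 a.u., and
    modest background noise.
    """

    n_probes_type1_red: int = 1200
    n_probes_type1_green: int = 1200
    n_probes_type2: int = 2400
    beta_weights: tuple[float, float, float] = (0.4, 0.2, 0.4)
    beta_shapes: tuple[tuple[float, float], ...] = ((2.0, 20.0), (5.0, 5.0), (20.0, 2.0))
    intensity_meanlog: float = float(np.log(6000.0))
    intensity_sdlog: float = 0.25
    background_sd: float = 40.0
    biological_sd: float = 0.015  # inter-individual beta variation per subject
    type2_bias: float = 0.2  # beta -> 0.5 + (beta-0.5)*(1-type2_bias)
    #: When True, type II probes follow the real channel layout (M read in
    #: green, U in red) so per-batch dye imbalance distorts their beta;
    #: when False both type II signals share the scale_type2/shift_type2 pair.
    type2_channel_split: bool = False
    n_samples: int = 1
    batch_effects: tuple[BatchEffect, ...] = (IDENTITY_BATCH,)
    batch_of_sample: tuple[int, ...] | None = None
    subject_of_sample: tuple[int, ...] | None = None
    group_of_sample: tuple[str, ...] | None = None
    covariate_values: tuple[float, ...] | None = None
    n_differential: int = 0
    delta_beta: float = 0.1
    n_covariate_probes: int = 0
    covariate_slope: float = 0.08
    covariate_noise_sd: float = 0.06
    n_adjacent_pairs: int = 0
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.beta_weights) - 1.0) > 1e-9:
            raise ValidationError("beta_weights must sum to 1")
        if self.background_sd < 0:
            raise ValidationError("background_sd must be >= 0")
        if self.biological_sd < 0:
            raise ValidationError("biological_sd must be >= 0")
        if not 0 <= self.type2_bias < 1:
            raise ValidationError("type2_bias must be in [0, 1)")
        for name in ("batch_of_sample", "subject_of_sample", "group_of_sample",
                     "covariate_values"):
            val = getattr(self, name)
            if val is not None and len(val) != self.n_samples:
                raise ValidationError(f"{name} must have length n_samples")
        if self.batch_of_sample is not None and max(self.batch_of_sample) >= len(
            self.batch_effects
        ):
            raise ValidationError("batch_of_sample indexes beyond batch_effects")


@dataclass
class GroundTruth:
    true_beta: pd.DataFrame = field(repr=False)
    sample_info: pd.DataFrame = field(repr=False)
    adjacent_pairs: list[tuple[str, str]] = field(default_factory=list)
    differential_probes: list[str] = field(default_factory=list)
    covariate_probes: list[str] = field(default_factory=list)


def _build_annotation(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n1r, n1g, n2 = cfg.n_probes_type1_red, cfg.n_probes_type1_green, cfg.n_probes_type2
    n = n1r + n1g + n2
    probe_ids = [f"cg{i:07d}" for i in range(n)]
    design = ["I"] * (n1r + n1g) + ["II"] * n2
    channel = ["red"] * n1r + ["green"] * n1g + ["none"] * n2
    cpg = rng.choice([1, 2, 3, 4], size=n, p=[0.45, 0.3, 0.15, 0.1])
    ann = pd.DataFrame(
        {
            "design_type": design,
            "channel": channel,
            "chromosome": "",
            "position": 0,
            "probe_cpg_count": cpg,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ann


def _assign_positions(
    ann: pd.DataFrame, pairs: list[tuple[str, str]]
) -> None:
    """One locus per probe (1 kb apart), pair members 5 bp apart."""
    partner = {a: b for a, b in pairs}
    paired_second = {b for _, b in pairs}
    chrom = np.empty(len(ann), dtype=object)
    pos = np.zeros(len(ann), dtype=int)
    loc = {}
    locus = 0
    idx = {p: i for i, p in enumerate(ann.index)}
    for p in ann.index:
        if p in paired_second:
            continue
        c = f"chr{1 + locus % 22}"
        base = 1000 * (1 + locus // 22)
        chrom[idx[p]] = c
        pos[idx[p]] = base
        loc[p] = (c, base)
        locus += 1
    for a, b in pairs:
        c, base = loc[a]
        chrom[idx[b]] = c
        pos[idx[b]] = base + 5
    ann["chromosome"] = chrom
    ann["position"] = pos


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[list[SignalSample], pd.DataFrame, GroundTruth]:
    """Generate signal samples, an annotation table, and the ground truth."""
    rng = np.random.default_rng(cfg.seed)
    ann = _build_annotation(cfg, rng)
    probes = ann.index
    n_probes = len(probes)
    n_samples = cfg.n_samples

    # adjacent pairs share one true-beta draw and sit 5 bp apart
    pairs: list[tuple[str, str]] = []
    if cfg.n_adjacent_pairs > 0:
        chosen = rng.choice(n_probes, size=2 * cfg.n_adjacent_pairs, replace=False)
        pairs = [
            (probes[chosen[2 * i]], probes[chosen[2 * i + 1]])
            for i in range(cfg.n_adjacent_pairs)
        ]
    _assign_positions(ann, pairs)

    batch_of_sample = np.asarray(
        cfg.batch_of_sample if cfg.batch_of_sample is not None else [0] * n_samples
    )
    subject_of_sample = np.asarray(
        cfg.subject_of_sample if cfg.subject_of_sample is not None else [0] * n_samples
    )
    subjects = np.unique(subject_of_sample)

    # per-probe population beta from the mixture; subjects scatter around it
    weights = np.asarray(cfg.beta_weights)
    comp = rng.choice(len(weights), size=n_probes, p=weights)
    probe_mean = np.empty(n_probes)
    for k, (a, b) in enumerate(cfg.beta_shapes):
        sel = comp == k
        probe_mean[sel] = rng.beta(a, b, size=int(sel.sum()))
    base = np.repeat(probe_mean[:, None], subjects.size, axis=1)
    if cfg.biological_sd > 0 and subjects.size > 1:
        base = np.clip(
            base + rng.normal(0.0, cfg.biological_sd, size=base.shape), 0.01, 0.99
        )
    pid_index = {p: i for i, p in enumerate(probes)}
    for a, b in pairs:
        base[pid_index[b], :] = base[pid_index[a], :]

    subject_col = {s: j for j, s in enumerate(subjects)}
    true_beta = base[:, [subject_col[s] for s in subject_of_sample]].copy()

    # covariate-linked probes: linear in the standardized covariate
    covariate_probe_ids: list[str] = []
    covariate = None
    if cfg.covariate_values is not None:
        covariate = np.asarray(cfg.covariate_values, dtype=float)
    if cfg.n_covariate_probes > 0:
        if covariate is None:
            raise ValidationError("covariate probes requested without covariate_values")
        z = (covariate - covariate.mean()) / (covariate.std() or 1.0)
        chosen = rng.choice(n_probes, size=cfg.n_covariate_probes, replace=False)
        covariate_probe_ids = list(probes[chosen])
        anchor = rng.uniform(0.15, 0.85, size=cfg.n_covariate_probes)
        eps = rng.normal(0.0, cfg.covariate_noise_sd, size=(cfg.n_covariate_probes, n_samples))
        true_beta[chosen, :] = np.clip(
            anchor[:, None] + cfg.covariate_slope * z[None, :] + eps, 0.01, 0.99
        )

    # case/control differential probes
    differential_ids: list[str] = []
    groups = cfg.group_of_sample
    if cfg.n_differential > 0:
        if groups is None:
            raise ValidationError("differential probes requested without group labels")
        is_case = np.asarray([g == "case" for g in groups])
        chosen = rng.choice(n_probes, size=cfg.n_differential, replace=False)
        differential_ids = list(probes[chosen])
        sign = np.where(np.arange(cfg.n_differential) % 2 == 0, 1.0, -1.0)
        shift = sign[:, None] * cfg.delta_beta * is_case[None, :].astype(float)
        true_beta[chosen, :] = np.clip(true_beta[chosen, :] + shift, 0.01, 0.99)

    # per-probe total intensity, shared across samples
    T = rng.lognormal(cfg.intensity_meanlog, cfg.intensity_sdlog, size=n_probes)

    is_t2 = (ann["design_type"] == "II").to_numpy()
    is_red = (ann["channel"] == "red").to_numpy()
    is_green = (ann["channel"] == "green").to_numpy()

    sample_ids = [f"S{j:03d}" for j in range(n_samples)]
    samples = []
    for j, sid in enumerate(sample_ids):
        beta_meas = true_beta[:, j].copy()
        beta_meas[is_t2] = 0.5 + (beta_meas[is_t2] - 0.5) * (1.0 - cfg.type2_bias)
        m = beta_meas * T
        u = (1.0 - beta_meas) * T
        if cfg.background_sd > 0:
            m = m + rng.normal(0.0, cfg.background_sd, size=n_probes)
            u = u + rng.normal(0.0, cfg.background_sd, size=n_probes)
        m = np.maximum(m, 0.0)
        u = np.maximum(u, 0.0)
        eff = cfg.batch_effects[batch_of_sample[j]]
        for mask, scale, shift in (
            (is_red, eff.scale_red, eff.shift_red),
            (is_green, eff.scale_green, eff.shift_green),
        ):
            m[mask] = scale * m[mask] + shift
            u[mask] = scale * u[mask] + shift
        if cfg.type2_channel_split:
            m[is_t2] = eff.scale_green * m[is_t2] + eff.shift_green
            u[is_t2] = eff.scale_red * u[is_t2] + eff.shift_red
        else:
            m[is_t2] = eff.scale_type2 * m[is_t2] + eff.shift_type2
            u[is_t2] = eff.scale_type2 * u[is_t2] + eff.shift_type2
        samples.append(
            SignalSample(sid, pd.DataFrame({"M": m, "U": u}, index=probes))
        )

    sample_info = pd.DataFrame(
        {
            "batch": batch_of_sample,
            "subject": subject_of_sample,
            "group": list(groups) if groups is not None else [""] * n_samples,
            "covariate": covariate if covariate is not None else np.nan,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = GroundTruth(
        true_beta=pd.DataFrame(true_beta, index=probes, columns=sample_ids),
        sample_info=sample_info,
        adjacent_pairs=pairs,
        differential_probes=differential_ids,
        covariate_probes=covariate_probe_ids,
    )
    return samples, ann, truth


def simulate_replicates(
    cfg: SimulationConfig,
    n_batches: int,
    n_reps: int,
    n_subjects: int = 1,
) -> tuple[list[SignalSample], pd.DataFrame, GroundTruth]:
    """Technical-replicate layouts: n_subjects biological samples, each
    assayed n_reps times, replicates spread round-robin over n_batches.

    Covers both benchmark layouts: one subject with many repeats, or several
    subjects with a few repeats each.  True beta is identical across a
    subject's replicates; batch distortions differ per batch (generated
    deterministically from the config seed when the config does not supply
    enough of them).
    """
    n_samples = n_subjects * n_reps
    batch = [r % n_batches for _ in range(n_subjects) for r in range(n_reps)]
    subject = [s for s in range(n_subjects) for _ in range(n_reps)]
    effects = cfg.batch_effects
    if len(effects) < n_batches:
        rng = np.random.default_rng(cfg.seed + 1)
        effects = random_batch_effects(n_batches, rng)
    cfg = replace(
        cfg,
        n_samples=n_samples,
        batch_effects=effects,
        batch_of_sample=tuple(batch),
        subject_of_sample=tuple(subject),
        group_of_sample=None,
        covariate_values=None,
    )
    return simulate_dataset(cfg)
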