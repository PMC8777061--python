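"""Desk-scale benchmark study designs.

Each function freezes one simulated analogue of a benchmark procedure as a
complete study design — sample layout, batch structure, effect probes —
parameterized only by a seed.  Tests and the acceptance script share these
definitions so the conditions cannot drift apart.

The batch distortions are of two magnitudes: within-study scanner drift
(scale within ~±40%, shifts of a few hundred a.u.) for the
technical-replicate and case-control designs, and cross-project
heterogeneity (scale up to ~1.5x, shifts up to ~900 a.u., and a wider
probe-intensity spread) for the regression design, which emulates pooling
independent cohorts.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .simulate import BatchEffect, SimulationConfig, simulate_dataset, simulate_replicates

__all__ = [
    "reference_cohort",
    "replicate_study",
    "case_control_study",
    "regression_study",
    "adjacent_pair_study",
    "CROSS_PROJECT_BATCHES",
]

#: Three fixed project-level distortions used by the case-control design.
CROSS_PROJECT_BATCHES = (
    BatchEffect(),
    BatchEffect(1.5, 800.0, 1.4, 900.0, 1.5, 850.0),
    BatchEffect(0.65, 300.0, 0.7, 250.0, 0.68, 280.0),
)

#: Variant with moderate channel-asymmetric (dye-bias) scaling for the
#: regression design, where type II probes read M and U in different channels.
DYE_BIAS_BATCHES = (
    BatchEffect(),
    BatchEffect(1.1, 400.0, 1.4, 700.0, 1.25, 550.0),
    BatchEffect(1.0, 400.0, 0.75, 250.0, 0.85, 320.0),
)


def reference_cohort(seed: int, n_samples: int = 8, **overrides):
    """Clean (single-batch) cohort used to fit the reference distribution."""
    cfg = SimulationConfig(n_samples=n_samples, seed=seed, **overrides)
    return simulate_dataset(cfg)


def replicate_study(
    seed: int,
    n_batches: int = 3,
    n_reps: int = 56,
    n_subjects: int = 1,
):
    """Technical-replicate layout: one or more subjects, repeats across batches.

    Defaults give the 1-subject x 56-replicate x 3-batch layout; pass
    ``n_subjects=9, n_reps=3`` for the few-subjects/few-reps layout.  The
    three batches carry the fixed strong project-level distortions.
    """
    cfg = SimulationConfig(seed=seed, batch_effects=CROSS_PROJECT_BATCHES[:n_batches])
    return simulate_replicates(cfg, n_batches=n_batches, n_reps=n_reps, n_subjects=n_subjects)


def case_control_study(
    seed: int,
    n_per_group: int = 30,
    frac_differential: float = 0.01,
    delta_beta: float = 0.1,
    clean: bool = False,
):
    """Case/control design with batch confounded with the train/test split.

    The training two-thirds of each group comes from a clean batch (as in
    a study whose training samples share the same chips); the test
    third has cases and controls on two different distorted batches, the
    situation where batch effects corrupt train/test consistency.
    ``clean=True`` keeps the layout but removes all batch distortion (the
    null-simulation variant used to calibrate the consistency metric).
    Returns ``(samples, annotation, truth, train_ids, test_ids)``.
    """
    n_train = 2 * n_per_group // 3
    groups = ("case",) * n_per_group + ("control",) * n_per_group
    batch = [0] * n_train + [1] * (n_per_group - n_train)
    batch += [0] * n_train + [2] * (n_per_group - n_train)
    effects = (BatchEffect(),) * 3 if clean else CROSS_PROJECT_BATCHES
    cfg = SimulationConfig(
        n_samples=2 * n_per_group,
        seed=seed,
        group_of_sample=groups,
        batch_effects=effects,
        batch_of_sample=tuple(batch),
        subject_of_sample=tuple(range(2 * n_per_group)),
        delta_beta=delta_beta,
        intensity_sdlog=0.6,
    )
    n_probes = cfg.n_probes_type1_red + cfg.n_probes_type1_green + cfg.n_probes_type2
    cfg = replace(cfg, n_differential=max(1, round(frac_differential * n_probes)))
    samples, ann, truth = simulate_dataset(cfg)
    ids = list(truth.true_beta.columns)
    train = ids[:n_train] + ids[n_per_group : n_per_group + n_train]
    test = ids[n_train:n_per_group] + ids[n_per_group + n_train :]
    return samples, ann, truth, train, test


def regression_study(
    seed: int,
    n_samples: int = 45,
    n_covariate_probes: int = 100,
):
    """Age-regression design pooling three 'projects' with strong distortions.

    Ages are uniform on [15, 90] and independent of project membership;
    project assignment is round-robin so each project is age-balanced.  The
    wider probe-intensity spread (sdlog 0.6) makes low-intensity probes
    batch-vulnerable, as on real arrays.
    """
    rng = np.random.default_rng(seed)
    ages = tuple(rng.uniform(15.0, 90.0, n_samples))
    cfg = SimulationConfig(
        n_samples=n_samples,
        seed=seed,
        covariate_values=ages,
        batch_effects=DYE_BIAS_BATCHES,
        batch_of_sample=tuple(int(i % 3) for i in range(n_samples)),
        subject_of_sample=tuple(range(n_samples)),
        n_covariate_probes=n_covariate_probes,
        intensity_sdlog=0.6,
        type2_channel_split=True,
    )
    return simulate_dataset(cfg)


def adjacent_pair_study(
    seed: int,
    n_samples: int = 6,
    n_pairs: int = 150,
):
    """Adjacent-CpG design: probe pairs <10 bp apart sharing one true beta,
    samples spread over three distorted batches."""
    rng = np.random.default_rng(seed)
    from .simulate import random_batch_effects

    effects = random_batch_effects(3, rng)
    cfg = SimulationConfig(
        n_samples=n_samples,
        seed=seed,
        batch_effects=effects,
        batch_of_sample=tuple(int(i % 3) for i in range(n_samples)),
        n_adjacent_pairs=n_pairs,
    )
    return simulate_dataset(cfg)
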