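"""Reference distribution: build, serialize, load.

The between-array step maps each sample's per-channel Infinium I intensity
mixture onto a fixed target — the reference distribution.  A reference is
one fitted two-component Gaussian mixture per color channel.  It is built
from a cohort by taking, for every Infinium I probe, the median across
samples of its methylated and of its unmethylated intensity, pooling those
per-probe medians per color channel (both signals of a type I probe are
read in the same channel), and fitting the mixture to the pooled vector.
Alternatively the eight Gaussian parameters can be supplied directly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ReferenceBuildError, SchemaError, ValidationError
from .io_signals import SignalSample
from .mixtures import ChannelMixture, GaussianComponent, fit_gmm2

__all__ = [
    "ReferenceModel",
    "build_reference",
    "save_reference",
    "load_reference",
    "make_reference_from_params",
]

SCHEMA_VERSION = "1.0"
log = logging.getLogger(__name__)


@dataclass
class ReferenceModel:
    red: ChannelMixture
    green: ChannelMixture
    n_samples: int = 0
    probe_counts: dict = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION
    provenance: str = ""

    def mixture(self, channel: str) -> ChannelMixture:
        if channel not in ("red", "green"):
            raise ValidationError(f"unknown channel {channel!r}")
        return self.red if channel == "red" else self.green


def _pool_channel_medians(
    samples: list[SignalSample], annotation: pd.DataFrame, channel: str
) -> np.ndarray:
    probes = annotation.index[
        (annotation["design_type"] == "I") & (annotation["channel"] == channel)
    ]
    if len(probes) == 0:
        raise ReferenceBuildError(f"no Infinium I probes on the {channel} channel")
    m_cols = []
    u_cols = []
    for s in samples:
        frame = s.signals.reindex(probes)
        frac_missing = frame.isna().any(axis=1).mean()
        if frac_missing > 0.5:
            log.warning(
                "sample %s is missing %.0f%% of %s-channel type I probes; retained",
                s.sample_id,
                100 * frac_missing,
                channel,
            )
        m_cols.append(frame["M"])
        u_cols.append(frame["U"])
    med_m = pd.concat(m_cols, axis=1).median(axis=1, skipna=True)
    med_u = pd.concat(u_cols, axis=1).median(axis=1, skipna=True)
    pooled = np.concatenate([med_m.to_numpy(float), med_u.to_numpy(float)])
    return pooled[np.isfinite(pooled)]


def build_reference(
    samples: list[SignalSample],
    annotation: pd.DataFrame,
    provenance: str = "",
) -> ReferenceModel:
    """Fit the per-channel reference mixtures from per-probe median intensities."""
    if len(samples) < 1:
        raise ReferenceBuildError("need at least one sample")
    mixtures = {}
    counts = {}
    for channel in ("red", "green"):
        pooled = _pool_channel_medians(samples, annotation, channel)
        if pooled.size < 50:
            raise ReferenceBuildError(
                f"only {pooled.size} pooled intensities on the {channel} channel"
            )
        mixtures[channel] = fit_gmm2(pooled, channel=channel)
        counts[channel] = int(pooled.size // 2)
    return ReferenceModel(
        red=mixtures["red"],
        green=mixtures["green"],
        n_samples=len(samples),
        probe_counts=counts,
        provenance=provenance,
    )


def _mixture_to_dict(mix: ChannelMixture) -> dict:
    return {
        "state1": {"mean": mix.state1.mean, "sd": mix.state1.sd, "weight": mix.state1.weight},
        "state2": {"mean": mix.state2.mean, "sd": mix.state2.sd, "weight": mix.state2.weight},
        "loglik": mix.loglik,
        "n_iter": mix.n_iter,
        "converged": mix.converged,
    }


def _mixture_from_dict(d: dict, channel: str) -> ChannelMixture:
    try:
        comps = [
            GaussianComponent(
                float(d[s]["mean"]), float(d[s]["sd"]), float(d[s]["weight"])
            )
            for s in ("state1", "state2")
        ]
    except KeyError as exc:
        raise SchemaError(f"reference file missing field {exc} for {channel} channel") from exc
    return ChannelMixture(
        state1=comps[0],
        state2=comps[1],
        channel=channel,
        loglik=float(d.get("loglik", float("nan"))),
        n_iter=int(d.get("n_iter", 0)),
        converged=bool(d.get("converged", True)),
    )


def save_reference(ref: ReferenceModel, path) -> None:
    doc = {
        "schema_version": ref.schema_version,
        "red": _mixture_to_dict(ref.red),
        "green": _mixture_to_dict(ref.green),
        "n_samples": ref.n_samples,
        "probe_counts": ref.probe_counts,
        "provenance": ref.provenance,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_reference(path) -> ReferenceModel:
    with open(path) as fh:
        doc = json.load(fh)
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"reference schema version mismatch: file has {version!r}, "
            f"this package reads {SCHEMA_VERSION!r}"
        )
    for channel in ("red", "green"):
        if channel not in doc:
            raise SchemaError(f"reference file missing the {channel} mixture")
    return ReferenceModel(
        red=_mixture_from_dict(doc["red"], "red"),
        green=_mixture_from_dict(doc["green"], "green"),
        n_samples=int(doc.get("n_samples", 0)),
        probe_counts=dict(doc.get("probe_counts", {})),
        schema_version=version,
        provenance=str(doc.get("provenance", "")),
    )


def make_reference_from_params(
    red_params: dict,
    green_params: dict,
    provenance: str = "user-supplied parameters",
) -> ReferenceModel:
    """Build a ReferenceModel from explicit per-channel Gaussian parameters.

    Each dict holds ``state1`` and ``state2`` sub-dicts with ``mean``,
    ``sd`` and ``weight``; state1.mean must be the smaller mean.
    """
    mixtures = {}
    for channel, params in (("red", red_params), ("green", green_params)):
        mix = _mixture_from_dict(params, channel)
        mix.converged = True
        mixtures[channel] = mix
    return ReferenceModel(
        red=mixtures["red"], green=mixtures["green"], provenance=provenance
    )
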