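"""Between-array normalization: the Gaussian-mixture quantile map.

Per color channel, the pooled methylated + unmethylated intensities of a
sample's Infinium I probes are fitted with a two-state Gaussian mixture.
Every intensity is hard-assigned to the state with the larger posterior and
mapped through

    rho = F(x | mu_state, sigma_state)        (sample fit)
    q   = F^{-1}(rho | mu_ref, sigma_ref)     (reference)

onto the same-numbered reference component.  Because both F and F^{-1} are
Gaussian, the composite is the affine map
``ref.mean + ref.sd * (x - src.mean) / src.sd``; the numeric CDF/inverse-CDF
path is implemented tail-symmetrically so the two agree to full double
precision.  Any per-channel affine distortion of the input (dye bias, batch
scale/shift) is absorbed by the sample fit and therefore removed.

Infinium II probes pass through this stage untouched; they are corrected
afterwards by the within-array step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FitError, GmqnError, ParameterError
from .io_signals import SignalSample
from .mixtures import ChannelMixture, GaussianComponent, fit_gmm2
from .reference import ReferenceModel
from scipy.special import ndtr, ndtri

__all__ = [
    "StateAssignment",
    "NormalizedSignals",
    "assign_states",
    "gmqn_map",
    "normalize_type1",
]

log = logging.getLogger(__name__)

#: Mapped intensities are floored here so beta stays defined.
INTENSITY_FLOOR = 1.0


@dataclass
class StateAssignment:
    """Hard state labels (1 or 2) and the posterior of the chosen state."""

    state: np.ndarray
    posterior_prob: np.ndarray


@dataclass
class NormalizedSignals:
    """GMQN-normalized intensities plus the per-sample fits used, for audit."""

    sample_id: str
    signals: pd.DataFrame = field(repr=False)
    red_fit: ChannelMixture | None = None
    green_fit: ChannelMixture | None = None

    def to_sample(self) -> SignalSample:
        return SignalSample(self.sample_id, self.signals[["M", "U"]].copy())


def assign_states(values, mix: ChannelMixture) -> StateAssignment:
    """Maximum-posterior state assignment; exact ties go to state 1."""
    x = np.asarray(values, dtype=float)
    means, sds, weights = mix.means, mix.sds, mix.weights
    z = (x[None, :] - means[:, None]) / sds[:, None]
    logp = np.log(weights)[:, None] - np.log(sds)[:, None] - 0.5 * z * z
    # posterior of state 2 vs state 1
    d = logp[1] - logp[0]
    post2 = 1.0 / (1.0 + np.exp(-d))
    state = np.where(d > 0, 2, 1)
    posterior = np.where(state == 2, post2, 1.0 - post2)
    return StateAssignment(state=state, posterior_prob=posterior)


def gmqn_map(values, src: GaussianComponent, ref: GaussianComponent, floor: float = INTENSITY_FLOOR):
    """Quantile-map values from the source Gaussian onto the reference Gaussian.

    Computed via the normal CDF and inverse CDF, evaluated in the nearer
    tail so that precision is preserved far from the mean; equals the
    affine form ref.mean + ref.sd*(x-src.mean)/src.sd to ~1e-14 relative.
    """
    if src.sd <= 0 or ref.sd <= 0:
        raise ParameterError("source and reference sds must be positive")
    x = np.asarray(values, dtype=float)
    z = (x - src.mean) / src.sd
    p_lower_tail = ndtr(-np.abs(z))
    q = ref.mean - np.sign(z) * ref.sd * ndtri(p_lower_tail)
    return np.maximum(q, floor)


def normalize_type1(
    sample: SignalSample,
    annotation: pd.DataFrame,
    ref: ReferenceModel,
    tol: float = 1e-6,
    max_iter: int = 1000,
    floor: float = INTENSITY_FLOOR,
) -> NormalizedSignals:
    """Normalize one sample's Infinium I intensities onto the reference.

    Per channel the sample's pooled M and U intensities are fitted, each
    value is assigned a state, and mapped onto the same-numbered reference
    component.  Probes with a missing M or U get both outputs missing; type
    II probes and probes absent from the annotation pass through unchanged
    (the latter with a logged warning).
    """
    out = sample.signals[["M", "U"]].astype(float).copy()
    unknown = out.index.difference(annotation.index)
    if len(unknown) > 0:
        log.warning(
            "sample %s: %d probes absent from the annotation pass through unchanged",
            sample.sample_id,
            len(unknown),
        )
    ann = annotation.reindex(out.index)
    fits: dict[str, ChannelMixture] = {}
    for channel in ("red", "green"):
        mask = (ann["design_type"] == "I") & (ann["channel"] == channel)
        probes = out.index[mask]
        if len(probes) == 0:
            continue
        frame = out.loc[probes]
        complete = ~frame.isna().any(axis=1)
        pooled = np.concatenate(
            [frame.loc[complete, "M"].to_numpy(), frame.loc[complete, "U"].to_numpy()]
        )
        if pooled.size < 100:  # >= 50 type I probes per channel
            raise FitError(
                f"sample {sample.sample_id}: too few complete type I probes "
                f"on the {channel} channel ({complete.sum()})"
            )
        try:
            mix = fit_gmm2(pooled, tol=tol, max_iter=max_iter, channel=channel)
        except GmqnError as exc:
            raise FitError(
                f"sample {sample.sample_id}: GMM fit failed on the {channel} channel: {exc}"
            ) from exc
        fits[channel] = mix
        ref_mix = ref.mixture(channel)
        assignment = assign_states(pooled, mix)
        mapped = np.empty_like(pooled)
        for state, src_comp, ref_comp in (
            (1, mix.state1, ref_mix.state1),
            (2, mix.state2, ref_mix.state2),
        ):
            sel = assignment.state == state
            if sel.any():
                mapped[sel] = gmqn_map(pooled[sel], src_comp, ref_comp, floor=floor)
        n_complete = int(complete.sum())
        out.loc[probes[complete], "M"] = mapped[:n_complete]
        out.loc[probes[complete], "U"] = mapped[n_complete:]
        incomplete = probes[~complete]
        out.loc[incomplete, ["M", "U"]] = np.nan
    return NormalizedSignals(
        sample_id=sample.sample_id,
        signals=out,
        red_fit=fits.get("red"),
        green_fit=fits.get("green"),
    )
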