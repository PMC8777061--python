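"""Within-array Infinium II probe-design-bias correction.

Infinium II probes read methylated and unmethylated signal in different
chemistry and are known to compress beta toward 0.5 relative to Infinium I
probes.  After the between-array step the Infinium I probes are on the
reference scale and serve as the fixed anchor; two corrections move type II
onto them:

* ``bmiq_adjust`` — BMIQ on beta-values: three-state (U/H/M) beta mixtures
  are fitted separately to type I and type II beta; type II probes are
  assigned a state and quantile-mapped (U and M states) or affinely
  stretched (H state) onto the corresponding type I component.
* ``swan_adjust`` — SWAN on intensities: probes are stratified by the CpG
  count in the probe body (capped at 3+); within each stratum each type II
  M and U intensity is replaced by the type I empirical quantile at its
  own within-stratum quantile.

Both leave type I probes untouched by construction, are monotone within
their pieces, and fall back to returning their input (with a logged
warning) if a fit fails — the between-array output is already usable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import betaln
from scipy.stats import beta as beta_dist
from scipy.stats import rankdata

from .between_array import NormalizedSignals, normalize_type1
from .errors import GmqnError, ParameterError
from .io_signals import BetaVector, SignalSample, compute_beta
from .mixtures import BetaComponent, BetaMixture3, fit_beta_mixture3
from .reference import ReferenceModel

__all__ = ["bmiq_adjust", "swan_adjust", "normalize_pipeline"]

log = logging.getLogger(__name__)

_EPS = 1e-6
#: BMIQ fits are run on at most this many values (deterministic thinning of
#: the sorted vector); the transform is applied to all probes.
BMIQ_FIT_SUBSAMPLE = 50_000


def _thin_sorted(x: np.ndarray, cap: int = BMIQ_FIT_SUBSAMPLE) -> np.ndarray:
    xs = np.sort(x)
    if xs.size <= cap:
        return xs
    idx = np.linspace(0, xs.size - 1, cap).round().astype(int)
    return xs[idx]


def _log_weighted_pdf(x, comp: BetaComponent):
    x = np.asarray(x, dtype=float)
    return (
        np.log(comp.weight)
        + (comp.a - 1.0) * np.log(x)
        + (comp.b - 1.0) * np.log1p(-x)
        - betaln(comp.a, comp.b)
    )


def _state_boundary(mix: BetaMixture3, left: str, right: str) -> float:
    """beta where the weighted densities of two adjacent components cross."""
    lo_comp, hi_comp = mix.components[left], mix.components[right]
    lo, hi = lo_comp.mean, hi_comp.mean

    def diff(x):
        return float(_log_weighted_pdf(x, lo_comp) - _log_weighted_pdf(x, hi_comp))

    a, b = lo + 1e-9, hi - 1e-9
    try:
        if diff(a) > 0 and diff(b) < 0:
            return float(brentq(diff, a, b, xtol=1e-10))
    except ValueError:  # pragma: no cover - brentq bracket failure
        pass
    return float(0.5 * (lo + hi))


def _quantile_map(x, src: BetaComponent, dst: BetaComponent):
    p = beta_dist.cdf(x, src.a, src.b)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return beta_dist.ppf(p, dst.a, dst.b)


def bmiq_adjust(beta: BetaVector, annotation: pd.DataFrame) -> BetaVector:
    """BMIQ correction of Infinium II beta anchored on Infinium I beta.

    Type II probes are assigned U/H/M by the posterior-crossing boundaries
    of the type II fit; U and M states are beta-quantile-mapped onto the
    type I U and M components, and the H state is stretched affinely so the
    type II U-H and H-M boundaries land on the type I boundaries.  Class
    images are clipped to the type I boundary intervals, which makes the
    composite map monotone on [0,1].  Type I beta is returned unchanged.
    """
    values = beta.values.copy()
    ann = annotation.reindex(values.index)
    is_t1 = (ann["design_type"] == "I").to_numpy()
    is_t2 = (ann["design_type"] == "II").to_numpy()
    b = values.to_numpy(float)
    ok = np.isfinite(b)
    t1_vals = b[is_t1 & ok]
    t2_vals = b[is_t2 & ok]
    try:
        mix1 = fit_beta_mixture3(_thin_sorted(np.clip(t1_vals, _EPS, 1 - _EPS)))
        mix2 = fit_beta_mixture3(_thin_sorted(np.clip(t2_vals, _EPS, 1 - _EPS)))
    except GmqnError as exc:
        log.warning("sample %s: BMIQ beta-mixture fit failed (%s); input returned",
                    beta.sample_id, exc)
        return BetaVector(beta.sample_id, values)

    t_uh1 = _state_boundary(mix1, "U", "H")
    t_hm1 = _state_boundary(mix1, "H", "M")
    t_uh2 = _state_boundary(mix2, "U", "H")
    t_hm2 = _state_boundary(mix2, "H", "M")

    x = np.clip(b[is_t2 & ok], _EPS, 1 - _EPS)
    out = np.empty_like(x)
    in_u = x < t_uh2
    in_m = x > t_hm2
    in_h = ~(in_u | in_m)
    if in_u.any():
        out[in_u] = np.clip(_quantile_map(x[in_u], mix2.U, mix1.U), 0.0, t_uh1)
    if in_m.any():
        out[in_m] = np.clip(_quantile_map(x[in_m], mix2.M, mix1.M), t_hm1, 1.0)
    if in_h.any():
        slope = (t_hm1 - t_uh1) / (t_hm2 - t_uh2)
        out[in_h] = t_uh1 + (x[in_h] - t_uh2) * slope

    new = b.copy()
    new[is_t2 & ok] = np.clip(out, 0.0, 1.0)
    return BetaVector(beta.sample_id, pd.Series(new, index=values.index))


def _stratum_of(cpg_count: pd.Series) -> pd.Series:
    return cpg_count.clip(lower=1, upper=3)


def swan_adjust(signals: NormalizedSignals, annotation: pd.DataFrame) -> NormalizedSignals:
    """SWAN-style intensity correction, type II onto fixed type I quantiles.

    For M and U separately, within each CpG-count stratum (1, 2, 3+), each
    type II intensity is replaced by the type I empirical quantile (linear
    interpolation between order statistics) at that probe's within-stratum
    quantile; within-stratum rank order of type II is preserved.  A stratum
    without type I probes falls back to the all-probes type I quantile map.
    """
    frame = signals.signals[["M", "U"]].astype(float).copy()
    ann = annotation.reindex(frame.index)
    is_t1 = (ann["design_type"] == "I").to_numpy()
    is_t2 = (ann["design_type"] == "II").to_numpy()
    strata = _stratum_of(ann["probe_cpg_count"]).to_numpy()

    for col in ("M", "U"):
        x = frame[col].to_numpy(float)
        ok = np.isfinite(x)
        t1_all = np.sort(x[is_t1 & ok])
        if t1_all.size == 0:
            log.warning("sample %s: no type I intensities; SWAN skipped", signals.sample_id)
            return signals
        new = x.copy()
        for s in np.unique(strata[is_t2]):
            sel2 = is_t2 & ok & (strata == s)
            if not sel2.any():
                continue
            sel1 = is_t1 & ok & (strata == s)
            target = np.sort(x[sel1]) if sel1.sum() >= 2 else t1_all
            if sel1.sum() < 2:
                log.warning(
                    "sample %s: stratum %s lacks type I probes; all-probe fallback",
                    signals.sample_id,
                    s,
                )
            vals = x[sel2]
            ranks = rankdata(vals, method="ordinal")
            p = (ranks - 0.5) / vals.size
            new[sel2] = np.quantile(target, p, method="linear")
        frame[col] = new

    return NormalizedSignals(
        sample_id=signals.sample_id,
        signals=frame,
        red_fit=signals.red_fit,
        green_fit=signals.green_fit,
    )


def normalize_pipeline(
    sample: SignalSample,
    annotation: pd.DataFrame,
    ref: ReferenceModel,
    method: str = "none",
    offset: float = 0.0,
    **fit_kwargs,
) -> BetaVector:
    """Full normalization of one sample: between-array, beta, within-array.

    ``method`` selects the within-array correction: ``"none"`` (between-array
    only), ``"bmiq"`` (BMIQ on beta) or ``"swan"`` (SWAN on intensities,
    then beta).
    """
    if method not in ("none", "bmiq", "swan"):
        raise ParameterError(f"method must be none, bmiq or swan; got {method!r}")
    normalized = normalize_type1(sample, annotation, ref, **fit_kwargs)
    if method == "swan":
        normalized = swan_adjust(normalized, annotation)
    beta = compute_beta(normalized.to_sample(), offset=offset)
    if method == "bmiq":
        beta = bmiq_adjust(beta, annotation)
    return beta
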