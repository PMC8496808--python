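"""Two-colour array processing: log ratios, normalization, replicate
aggregation and threshold CNV calls.

The pipeline is raw log2(test/ref) -> between-channel normalization ->
optional GC-loess correction -> mean-then-median replicate aggregation
-> +/-0.8 threshold calls. Normalization never changes probe count or
order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .exceptions import ConfigError, DataError
from .synthio import ARRAY_IDS, DEFAULT_DESIGN


@dataclass(frozen=True)
class CallThreshold:
    """Magnitude of the symmetric log2-ratio threshold for gain/loss calls."""

    magnitude: float = 0.8

    def __post_init__(self) -> None:
        if self.magnitude <= 0:
            raise ConfigError("call threshold must be positive")


def signals_wide(signals: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot the long signal table into (test, ref) probe x array matrices."""
    bad = signals[(signals["test_intensity"] <= 0) | (signals["ref_intensity"] <= 0)]
    if len(bad):
        r = bad.iloc[0]
        raise DataError(
            f"non-positive intensity for probe {r['probe_id']!r} on array {r['array_id']!r}"
        )
    test = signals.pivot(index="probe_id", columns="array_id", values="test_intensity")
    ref = signals.pivot(index="probe_id", columns="array_id", values="ref_intensity")
    if test.isna().any().any() or ref.isna().any().any():
        missing = test.index[test.isna().any(axis=1)]
        raise DataError(f"probe(s) missing from some array: {list(missing[:3])} ...")
    # preserve first-appearance probe order
    order = signals["probe_id"].drop_duplicates()
    return test.loc[order], ref.loc[order]


def raw_log_ratios(signals: pd.DataFrame) -> pd.DataFrame:
    """Per-probe, per-array log2(test/ref)."""
    test, ref = signals_wide(signals)
    return np.log2(test) - np.log2(ref)


def quantile_match_channels(signals: pd.DataFrame) -> pd.DataFrame:
    """Map both channels of each array onto their mean quantile distribution.

    Removes channel-wide monotone distributional distortion (a stand-in
    for scanner/label intensity response differences). Note this assumes
    the two channels carry comparable overall distributions and will
    attenuate genuine large-scale copy-number signal; see the methods
    note for when to prefer plain median-centering.
    """
    test, ref = signals_wide(signals)
    out = signals.copy()
    for array_id in test.columns:
        t = test[array_id].to_numpy()
        r = ref[array_id].to_numpy()
        target = (np.sort(t) + np.sort(r)) / 2.0
        t_new = target[np.argsort(np.argsort(t))]
        r_new = target[np.argsort(np.argsort(r))]
        m = out["array_id"] == array_id
        idx = out.loc[m, "probe_id"]
        t_map = pd.Series(t_new, index=test.index)
        r_map = pd.Series(r_new, index=ref.index)
        out.loc[m, "test_intensity"] = t_map.loc[idx].to_numpy()
        out.loc[m, "ref_intensity"] = r_map.loc[idx].to_numpy()
    return out


def between_channel_normalize(signals: pd.DataFrame, method: str = "median") -> pd.DataFrame:
    """Channel normalization returning a probe x array log2-ratio matrix.

    ``method="median"`` centers each array's log ratios at zero (exact
    identity when the majority of probes are copy-neutral at ratio 0).
    ``method="quantile"`` first quantile-matches the two channel
    distributions, then median-centers.
    """
    if method not in ("median", "quantile"):
        raise ConfigError(f"unknown normalization method {method!r}")
    if signals["probe_id"].nunique() < 2:
        raise DataError("need at least 2 probes to normalize")
    if method == "quantile":
        signals = quantile_match_channels(signals)
    ratios = raw_log_ratios(signals)
    return ratios - ratios.median(axis=0)


def gc_loess_normalize(
    ratios: pd.DataFrame | pd.Series,
    gc: pd.Series,
    span: float = 0.3,
    iterations: int = 2,
) -> pd.DataFrame | pd.Series:
    """Subtract a loess fit of ratio on probe GC fraction, per array.

    ``span`` is the loess smoothing fraction in (0, 1]; tricube weights
    with ``iterations`` robustness iterations (statsmodels lowess).
    """
    if not 0 < span <= 1:
        raise ConfigError("loess span must lie in (0, 1]")
    single = isinstance(ratios, pd.Series)
    frame = ratios.to_frame() if single else ratios
    gc = gc.reindex(frame.index)
    if gc.isna().any():
        raise DataError("GC fraction missing for some probes")
    if ((gc < 0) | (gc > 1)).any():
        raise DataError("GC fractions must lie in [0, 1]")
    if len(frame) < 10:
        raise ConfigError("too few probes for a local GC fit")
    x = gc.to_numpy(dtype=float)
    out = {}
    for col in frame.columns:
        y = frame[col].to_numpy(dtype=float)
        fit = lowess(y, x, frac=span, it=iterations, xvals=x)
        out[col] = y - fit
    res = pd.DataFrame(out, index=frame.index)
    return res.iloc[:, 0].rename(ratios.name) if single else res


def aggregate_weighted_median(
    ratios: pd.DataFrame, design: dict | None = None
) -> pd.Series:
    """Mean-then-median replicate aggregation.

    Per probe: average the technical-replicate pair, then take the
    median of that mean and the two remaining biological arrays.
    """
    design = design or DEFAULT_DESIGN
    t1, t2 = design["tech_pair"]
    b1, b2 = design["bio"]
    for a in (t1, t2, b1, b2):
        if a not in ratios.columns:
            raise DataError(f"array {a!r} missing from ratio matrix")
        if ratios[a].isna().any():
            raise DataError(f"array {a!r} has missing probe values")
    tech_mean = (ratios[t1] + ratios[t2]) / 2.0
    stacked = np.column_stack([tech_mean, ratios[b1], ratios[b2]])
    return pd.Series(np.median(stacked, axis=1), index=ratios.index, name="acgh_ratio")


def call_acgh(ratios: pd.Series, threshold: CallThreshold | float = CallThreshold()) -> pd.Series:
    """Gain/neutral/loss call per probe; strict threshold exceedance.

    Positive ratios are species-A-biased (gain) under the A/B orientation.
    """
    mag = threshold.magnitude if isinstance(threshold, CallThreshold) else float(threshold)
    if mag <= 0:
        raise ConfigError("call threshold must be positive")
    calls = np.where(ratios > mag, "gain", np.where(ratios < -mag, "loss", "neutral"))
    return pd.Series(calls, index=ratios.index, name="call")


def process_signals(
    signals: pd.DataFrame,
    gc: pd.Series | None = None,
    method: str = "median",
    gc_span: float = 0.3,
    apply_gc: bool = False,
    design: dict | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Convenience: signals -> (normalized per-array ratios, aggregated ratio)."""
    ratios = between_channel_normalize(signals, method=method)
    ratios = ratios[list(ARRAY_IDS)]
    if apply_gc:
        if gc is None:
            raise ConfigError("GC fractions required for GC-loess normalization")
        ratios = gc_loess_normalize(ratios, gc, span=gc_span)
    return ratios, aggregate_weighted_median(ratios, design)
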