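"""Reading and writing of signal tables, probe annotations and beta matrices.

The interchange format is a delimited text table (TSV by default): the first
column holds probe identifiers, followed by one ``<sample>.Methylated`` /
``<sample>.Unmethylated`` column pair per array.  This mirrors what
minfi-style preprocessing or GEO supplementary files export for arrays whose
raw IDAT files were never deposited.  No binary formats are read.

Probe annotations carry the Infinium design type (I or II), the color channel
for type I probes (both the methylated and unmethylated bead of a type I
probe are read in a single channel, red or green), 1-based genomic
coordinates and the CpG count in the probe body (used by SWAN-style
stratification).

The methylation level of a probe is the beta-value

    beta = M / (M + U + offset)

with ``offset = 0`` by default.  Missing cells propagate as missing through
every downstream step; nothing is imputed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, SchemaError, ValidationError

__all__ = [
    "SignalSample",
    "BetaVector",
    "read_signal_table",
    "write_signal_table",
    "read_annotation",
    "validate_annotation",
    "compute_beta",
    "write_beta_matrix",
    "read_beta_matrix",
]

#: Default regex matching per-sample signal columns. Must expose named groups
#: ``sample`` and ``kind`` (kind in {Methylated, Unmethylated}).
DEFAULT_COLUMN_PATTERN = r"^(?P<sample>.+)\.(?P<kind>Methylated|Unmethylated)$"

ANNOTATION_COLUMNS = (
    "probe_id",
    "design_type",
    "channel",
    "chromosome",
    "position",
    "probe_cpg_count",
)


@dataclass
class SignalSample:
    """Raw methylated/unmethylated intensities of one array.

    ``signals`` is a DataFrame indexed by probe id with float columns ``M``
    and ``U``; missing measurements are NaN.
    """

    sample_id: str
    signals: pd.DataFrame

    def __post_init__(self) -> None:
        if not {"M", "U"}.issubset(self.signals.columns):
            raise SchemaError(f"sample {self.sample_id}: signals need columns M and U")
        bad = (self.signals[["M", "U"]] < 0).any(axis=1)
        if bad.any():
            probe = self.signals.index[bad][0]
            raise ValidationError(
                f"negative intensity at probe {probe!r} in sample {self.sample_id!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.signals.index

    def copy(self) -> "SignalSample":
        return SignalSample(self.sample_id, self.signals.copy())


@dataclass
class BetaVector:
    """Per-probe beta-values of one sample; missing entries are NaN."""

    sample_id: str
    values: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        v = self.values.to_numpy(float)
        ok = np.isnan(v) | ((v >= 0.0) & (v <= 1.0))
        if not ok.all():
            raise ValidationError(
                f"beta values outside [0,1] in sample {self.sample_id!r}"
            )


def _sep_for(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


def read_signal_table(
    path,
    column_pattern: str = DEFAULT_COLUMN_PATTERN,
    sep: str | None = None,
) -> list[SignalSample]:
    """Parse a probe x (sample.Methylated, sample.Unmethylated) table.

    Column matching is whitespace-insensitive (headers are stripped) and
    order-insensitive.  Blank cells become NaN.  A sample with only one of
    the two signal columns raises :class:`SchemaError`.
    """
    try:
        df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse signal table {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"signal table {path} has no sample columns")
    df.index = df.index.astype(str).str.strip()
    pat = re.compile(column_pattern)
    columns: dict[str, dict[str, str]] = {}
    for col in df.columns:
        m = pat.match(str(col).strip())
        if m is None:
            raise SchemaError(f"column {col!r} does not match pattern {column_pattern!r}")
        kind = "M" if m.group("kind").lower().startswith("m") else "U"
        columns.setdefault(m.group("sample"), {})[kind] = col
    samples = []
    for sample_id, cols in columns.items():
        if set(cols) != {"M", "U"}:
            missing = "Unmethylated" if "U" not in cols else "Methylated"
            raise SchemaError(f"sample {sample_id!r} lacks a {missing} column")
        frame = pd.DataFrame(
            {
                "M": pd.to_numeric(df[cols["M"]], errors="coerce"),
                "U": pd.to_numeric(df[cols["U"]], errors="coerce"),
            },
            index=df.index,
        ).astype(float)
        samples.append(SignalSample(sample_id, frame))
    return samples


def write_signal_table(samples: list[SignalSample], path, sep: str | None = None) -> None:
    """Write samples back to the interchange table format (inverse of read)."""
    pieces = {}
    for s in samples:
        pieces[f"{s.sample_id}.Methylated"] = s.signals["M"]
        pieces[f"{s.sample_id}.Unmethylated"] = s.signals["U"]
    out = pd.DataFrame(pieces)
    out.index.name = "probe_id"
    out.to_csv(path, sep=_sep_for(path, sep), float_format="%.10g")


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize an annotation table (indexed by probe_id)."""
    required = set(ANNOTATION_COLUMNS) - {"probe_id"}
    missing = required - set(ann.columns)
    if missing:
        raise SchemaError(f"annotation missing columns: {sorted(missing)}")
    if ann.index.has_duplicates:
        dup = ann.index[ann.index.duplicated()][0]
        raise ValidationError(f"duplicate probe_id {dup!r} in annotation")
    ann = ann.copy()
    ann["design_type"] = ann["design_type"].astype(str).str.strip()
    ann["channel"] = ann["channel"].astype(str).str.strip().str.lower()
    bad_type = ~ann["design_type"].isin(["I", "II"])
    if bad_type.any():
        raise ValidationError(
            f"invalid design_type {ann.loc[bad_type, 'design_type'].iloc[0]!r}"
        )
    t1 = ann["design_type"] == "I"
    if not ann.loc[t1, "channel"].isin(["red", "green"]).all():
        probe = ann.index[t1 & ~ann["channel"].isin(["red", "green"])][0]
        raise ValidationError(f"type I probe {probe!r} must have channel red or green")
    if not (ann.loc[~t1, "channel"] == "none").all():
        probe = ann.index[~t1 & (ann["channel"] != "none")][0]
        raise ValidationError(f"type II probe {probe!r} must have channel 'none'")
    ann["position"] = ann["position"].astype(int)
    ann["probe_cpg_count"] = ann["probe_cpg_count"].astype(int)
    if (ann["probe_cpg_count"] < 0).any():
        raise ValidationError("probe_cpg_count must be >= 0")
    return ann


def read_annotation(path, sep: str | None = None) -> pd.DataFrame:
    """Read a probe annotation TSV/CSV with the six required columns."""
    try:
        ann = pd.read_csv(path, sep=_sep_for(path, sep))
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"cannot parse annotation {path}: {exc}") from exc
    ann.columns = [str(c).strip() for c in ann.columns]
    if "probe_id" not in ann.columns:
        raise SchemaError("annotation missing 'probe_id' column")
    ann = ann.set_index(ann["probe_id"].astype(str).str.strip()).drop(columns="probe_id")
    return validate_annotation(ann)


def write_annotation(ann: pd.DataFrame, path, sep: str | None = None) -> None:
    out = ann.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep=_sep_for(path, sep))


def compute_beta(sample: SignalSample, offset: float = 0.0) -> BetaVector:
    """beta = M / (M + U + offset); zero denominators become missing."""
    if offset < 0:
        raise ParameterError(f"offset must be >= 0, got {offset}")
    m = sample.signals["M"].to_numpy(float)
    u = sample.signals["U"].to_numpy(float)
    denom = m + u + offset
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, m / denom, np.nan)
    beta[np.isnan(m) | np.isnan(u)] = np.nan
    return BetaVector(sample.sample_id, pd.Series(beta, index=sample.signals.index))


def write_beta_matrix(betas: list[BetaVector], path, sep: str | None = None) -> None:
    """Write a probes x samples beta matrix."""
    out = pd.DataFrame({b.sample_id: b.values for b in betas})
    out.index.name = "probe_id"
    out.to_csv(path, sep=_sep_for(path, sep), float_format="%.8g")


def read_beta_matrix(path, sep: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    df.index = df.index.astype(str)
    return df.astype(float)
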