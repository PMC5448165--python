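"""Tables, sequences and the in-memory containers of the pipeline.

Expression matrices are plain delimited text: column 1 is the gene id and
every remaining column is named ``<condition>_<time_min>_<replicate>``
(conditions must not contain underscores).  pERK measurements are tidy
tables with condition/time_min/replicate/log2fc columns.  All output is
tab-separated with >= 12 significant digits so reader∘writer is the
identity within 1e-9; missing values are serialized as ``NA``.

The promoter utility scores pre-extracted FASTA windows (e.g. TSS ± 1,000
bp) for GC content; genome coordinate arithmetic is out of scope.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, TableParseError

__all__ = [
    "ExpressionMatrix",
    "PerkMeasurements",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_perk_table",
    "write_table",
    "read_table",
    "gc_content",
]

_SAMPLE_RE = re.compile(r"^(?P<condition>[^_]+)_(?P<time>[0-9.]+)_(?P<rep>\d+)$")


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) with sample metadata.

    ``values``: DataFrame indexed by gene id with sample-named columns.
    ``samples``: DataFrame indexed by sample name with condition (str),
    time (min, float) and replicate (int) columns.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise FormatError("sample columns and metadata rows disagree")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicated gene id {dup!r}")
        t = self.samples["time"]
        if not np.all(np.isfinite(t)) or (t < 0).any():
            raise FormatError("every sample needs a finite time >= 0")
        if (self.samples.loc[self.samples["condition"] == "UT", "time"] != 0).any():
            raise FormatError("untreated (UT) samples must have time 0")
        key = self.samples[["condition", "time", "replicate"]]
        if key.duplicated().any():
            raise FormatError("replicate labels must be unique within "
                              "(condition, time)")

    @property
    def gene_ids(self):
        return list(self.values.index)

    def drop_samples(self, names) -> "ExpressionMatrix":
        """Exclude flagged outlier samples (e.g. a contaminated replicate)."""
        keep = [c for c in self.values.columns if c not in set(names)]
        return ExpressionMatrix(values=self.values[keep],
                                samples=self.samples.loc[keep])


@dataclass
class PerkMeasurements:
    """pERK2 log2 fold-change measurements grouped by condition."""

    data: pd.DataFrame  # columns: condition, time, replicate, log2fc

    def __post_init__(self) -> None:
        required = {"condition", "time", "replicate", "log2fc"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"pERK table missing columns {sorted(missing)}")
        if len(self.data) == 0:
            raise FormatError("pERK table is empty")
        if not np.all(np.isfinite(self.data["log2fc"])):
            raise FormatError("log2fc values must be finite")
        for (cond, rep), grp in self.data.groupby(["condition", "replicate"]):
            t = grp["time"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise FormatError(
                    f"times not strictly increasing for condition {cond!r} "
                    f"replicate {rep}")

    @property
    def conditions(self):
        return list(self.data["condition"].unique())

    def for_condition(self, condition: str) -> pd.DataFrame:
        return self.data[self.data["condition"] == condition]


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _parse_sample_name(name: str):
    m = _SAMPLE_RE.match(name)
    if not m:
        raise FormatError(
            f"sample column {name!r} does not match "
            "'<condition>_<time_min>_<replicate>'")
    return m["condition"], float(m["time"]), int(m["rep"])


def read_expression_matrix(path, metadata_spec=None,
                           drop_samples=None) -> ExpressionMatrix:
    """Read a delimited expression table with metadata-encoding column names.

    Duplicate gene rows are collapsed by keeping the row with the highest
    mean across samples (the multi-probe-set rule).  Non-numeric cells
    raise a parse error naming the location.  ``metadata_spec`` may supply a
    sidecar metadata table (sample -> condition/time/replicate) overriding
    column-name parsing; ``drop_samples`` lists outliers to exclude.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                     na_values=["NA"], keep_default_na=False)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    values = pd.DataFrame(index=df.index, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col] != "")
        if bad.any():
            gene = df.index[bad][0]
            raise TableParseError(
                f"{path}: non-numeric value {df.loc[gene, col]!r} at "
                f"gene {gene!r}, column {col!r}")
        values[col] = converted
    if metadata_spec is not None:
        meta = pd.DataFrame(metadata_spec).loc[values.columns]
        missing = {"condition", "time", "replicate"} - set(meta.columns)
        if missing:
            raise FormatError(f"metadata missing fields {sorted(missing)}")
    else:
        parsed = [_parse_sample_name(c) for c in values.columns]
        meta = pd.DataFrame(parsed, index=values.columns,
                            columns=["condition", "time", "replicate"])
    if values.index.duplicated().any():
        means = values.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        values = values.iloc[order]
        values = values[~values.index.duplicated(keep="first")]
    matrix = ExpressionMatrix(values=values, samples=meta)
    if drop_samples:
        matrix = matrix.drop_samples(drop_samples)
    return matrix


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format="%.12g",
                         na_rep="NA", index_label="gene")


def read_perk_table(path) -> PerkMeasurements:
    """Read a tidy pERK table (condition, time_min, replicate, log2fc)."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, na_values=["NA"])
    if len(df) == 0:
        raise FormatError(f"{path}: empty pERK table")
    df = df.rename(columns={"time_min": "time"})
    return PerkMeasurements(data=df)


def write_table(records, path) -> None:
    """Write any result table as TSV, round-trippable to 1e-9.

    Floats use 15 significant digits; missing values become ``NA``.
    An empty record set is an error — silence would hide an upstream bug.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    if len(df) == 0:
        raise FormatError("refusing to write an empty table")
    index = df.index.name is not None
    df.to_csv(path, sep="\t", float_format="%.15g", na_rep="NA", index=index)


def read_table(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    sep = _sniff_sep(path)
    return pd.read_csv(path, sep=sep, na_values=["NA"])


_IUPAC = set("ACGTUWSMKRYBDHVN")
_GC_LETTERS = frozenset("GCS")


def gc_content(sequences, window: int | None = None) -> pd.Series:
    """GC fraction per record, counting G/C/S over non-N positions.

    ``sequences`` is a FASTA path or an iterable of (id, sequence) pairs /
    SeqRecords.  With ``window`` set, the central ``2*window`` bp of each
    record are scored (records supplied as pre-extracted promoter windows
    are scored whole by default).  An empty sequence yields a missing
    value, not zero.
    """
    if isinstance(sequences, (str, bytes)) or hasattr(sequences, "read"):
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(sequences, "fasta")]
    else:
        records = [(r.id, str(r.seq)) if hasattr(r, "seq") else (r[0], r[1])
                   for r in sequences]
    out = {}
    for name, seq in records:
        seq = seq.upper().replace("U", "T")
        bad = set(seq) - _IUPAC
        if bad:
            raise ValueError(f"record {name!r}: non-IUPAC letters {sorted(bad)}")
        if window is not None:
            if 2 * window > len(seq):
                raise ValueError(f"record {name!r}: window {window} exceeds "
                                 "record length")
            mid = len(seq) // 2
            seq = seq[max(mid - window, 0):mid + window]
        denom = sum(1 for c in seq if c != "N")
        if denom == 0:
            out[name] = math.nan
            continue
        out[name] = sum(1 for c in seq if c in _GC_LETTERS) / denom
    return pd.Series(out, name="gc_fraction")
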