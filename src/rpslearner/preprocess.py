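"""Expression-matrix IO and normalization.

Bulk RNA-seq expression profiles enter the pipeline as a samples × genes real
matrix.  Raw read counts are normalized within-sample to transcripts per
million (TPM, length-corrected abundances summing to 1e6) and then
log-transformed (log2(x + 1) by default); the classifier consumes the
log-scale matrix.  No quantile normalization or batch correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("rpslearner")

TPM_TOTAL = 1e6

#: processing stages an ExpressionMatrix can be in
STAGES = ("counts", "tpm", "log")


@dataclass
class ExpressionMatrix:
    """A samples × genes real matrix with ids and a processing stage.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_genes)
        Expression values; units depend on ``stage`` (raw counts, TPM, or
        log-TPM).
    sample_ids, gene_ids : list of str
        Ordered, unique axis identifiers.
    stage : {"counts", "tpm", "log"}
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    stage: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, d = self.values.shape
        if n != len(self.sample_ids) or d != len(self.gene_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} sample ids x {len(self.gene_ids)} gene ids"
            )
        for name, ids in (("sample", self.sample_ids), ("gene", self.gene_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValueError(f"duplicate {name} ids: {sorted(dupes)}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.stage in ("counts", "tpm") and np.any(self.values < 0):
            raise ValueError(f"stage={self.stage} values must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def subset_rows(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in np.atleast_1d(idx)],
        )


@dataclass
class LabelVector:
    """Per-sample class labels over a finite ordered label set.

    ``positive_class`` designates the class used for binary F1 and AUC.
    """

    labels: list[str]
    label_set: list[str] = field(default_factory=list)
    positive_class: str | None = None

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        if not self.label_set:
            self.label_set = sorted(set(self.labels))
        self.label_set = [str(x) for x in self.label_set]
        if len(set(self.label_set)) != len(self.label_set):
            raise ValueError("label_set contains duplicates")
        if len(self.label_set) < 2:
            raise ValueError("need at least 2 classes in label_set")
        extra = set(self.labels) - set(self.label_set)
        if extra:
            raise ValueError(f"labels outside label_set: {sorted(extra)}")
        if self.positive_class is None:
            # last label in the ordered set, mirroring sklearn's convention
            self.positive_class = self.label_set[-1]
        if self.positive_class not in self.label_set:
            raise ValueError(f"positive_class {self.positive_class!r} not in label_set")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.label_set)

    def as_int(self) -> np.ndarray:
        """Integer codes following label_set order."""
        lut = {c: i for i, c in enumerate(self.label_set)}
        return np.array([lut[x] for x in self.labels], dtype=int)


def _duplicates(ids) -> set:
    seen, dup = set(), set()
    for x in ids:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------- file IO


def load_expression(
    path,
    orientation: str = "samples_by_genes",
    delimiter: str = "\t",
    stage: str = "counts",
) -> ExpressionMatrix:
    """Read a delimited expression table into samples × genes orientation.

    The first row and first column are headers/ids.  ``orientation`` says how
    the *file* is laid out; the returned matrix is always samples × genes.
    """
    import io

    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    # pandas silently mangles duplicate column names, so check the raw header
    header_ids = text.splitlines()[0].split(delimiter)[1:]
    dup_cols = _duplicates(header_ids)
    if dup_cols:
        raise ValueError(f"duplicate column ids in {path}: {sorted(dup_cols)}")
    df = pd.read_csv(io.StringIO(text), sep=delimiter, index_col=0, header=0, dtype=str)
    if df.index.has_duplicates:
        raise ValueError(
            f"duplicate row ids in {path}: "
            f"{sorted(df.index[df.index.duplicated()].unique())}"
        )
    try:
        num = df.astype(float)
    except ValueError:
        for j, col in enumerate(df.columns):
            for i, (rid, cell) in enumerate(df[col].items()):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell {cell!r} at row {rid!r} "
                        f"(line {i + 2}), column {col!r} (field {j + 2})"
                    ) from None
        raise
    if orientation == "genes_by_samples":
        num = num.T
    return ExpressionMatrix(
        values=num.to_numpy(),
        sample_ids=list(num.index),
        gene_ids=list(num.columns),
        stage=stage,
    )


def save_expression(mat: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    """Write samples × genes with sample ids in the first column."""
    mat.to_frame().to_csv(path, sep=delimiter, index_label="sample_id")


def load_labels(path, delimiter: str = "\t", positive_class: str | None = None) -> LabelVector:
    """Read a two-column (sample_id, label) table; order follows the file."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} needs two columns (sample_id, label)")
    return LabelVector(labels=list(df.iloc[:, 1]), positive_class=positive_class)


def save_labels(labels: LabelVector, sample_ids: list[str], path, delimiter: str = "\t") -> None:
    pd.DataFrame({"sample_id": sample_ids, "label": labels.labels}).to_csv(
        path, sep=delimiter, index=False
    )


def load_gene_lengths(path, delimiter: str = "\t") -> dict[str, float]:
    """Read a two-column (gene_id, length_bases) table into a dict."""
    df = pd.read_csv(path, sep=delimiter, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"gene-length file {path} needs two columns (gene_id, length)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


# ------------------------------------------------------- normalization


def normalize_tpm(counts: ExpressionMatrix, gene_lengths) -> ExpressionMatrix:
    """Length-correct raw counts and rescale each sample to sum to 1e6.

    Per sample: ``rate_g = count_g / length_g``; ``TPM_g = 1e6 * rate_g /
    sum_g(rate_g)``.  Samples with all-zero counts come out all-zero (with a
    logged warning) rather than NaN.
    """
    if counts.stage != "counts":
        raise ValueError(f"normalize_tpm expects stage=counts, got {counts.stage}")
    if isinstance(gene_lengths, dict):
        missing = [g for g in counts.gene_ids if g not in gene_lengths]
        if missing:
            raise ValueError(f"missing gene lengths for: {missing[:10]}")
        lengths = np.array([gene_lengths[g] for g in counts.gene_ids], dtype=float)
    else:
        lengths = np.asarray(gene_lengths, dtype=float)
        if lengths.shape != (counts.n_genes,):
            raise ValueError(
                f"need one length per gene: got {lengths.shape}, expected ({counts.n_genes},)"
            )
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must all be positive")
    if np.any(counts.values < 0):
        raise ValueError("counts must be non-negative")

    rates = counts.values / lengths[None, :]
    totals = rates.sum(axis=1)
    zero = totals == 0
    if np.any(zero):
        logger.warning(
            "%d sample(s) with all-zero counts left as all-zero TPM rows", int(zero.sum())
        )
    safe = np.where(zero, 1.0, totals)
    tpm = TPM_TOTAL * rates / safe[:, None]
    tpm[zero] = 0.0
    return replace(counts, values=tpm, stage="tpm")


def log_transform(tpm: ExpressionMatrix, base: float = 2.0, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Elementwise log(x + pseudocount) in the given base (default log2(x+1))."""
    if tpm.stage == "log":
        raise ValueError("matrix is already log-transformed")
    if np.any(tpm.values < 0):
        raise ValueError("log_transform input must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    vals = np.log(tpm.values + pseudocount) / np.log(base)
    return replace(tpm, values=vals, stage="log")
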