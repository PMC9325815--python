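"""Marker quality control and genomic relationship (kinship) matrices.

Genotypes are biallelic dosage codes 0/1/2 (count of the alternative
allele) with NaN for missing calls.  The kinship matrix is VanRaden's
method 1: columns of the dosage matrix are centred by twice the allele
frequency and the cross-product is scaled by ``c = 2 * sum_j p_j (1 - p_j)``,
so that the mean diagonal tends to 1 for a population in Hardy-Weinberg
proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "KinshipMatrix",
    "QCReport",
    "filter_markers",
    "impute_missing",
    "vanraden_kinship",
    "read_genotype_csv",
    "read_genotype_vcf",
]


@dataclass
class MarkerMatrix:
    """Entries x markers dosage matrix.

    Parameters
    ----------
    entry_ids : sequence of str
        Unique entry labels (rows).
    dosages : ndarray, shape (N, P)
        Float array of codes in {0, 1, 2}; missing calls are NaN.
    marker_ids : sequence of str
        Unique marker labels (columns).
    """

    entry_ids: list
    dosages: np.ndarray
    marker_ids: list

    def __post_init__(self) -> None:
        self.entry_ids = list(self.entry_ids)
        self.marker_ids = list(self.marker_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, p = self.dosages.shape
        if len(self.entry_ids) != n or len(self.marker_ids) != p:
            raise ValueError("label lengths do not match dosage matrix shape")
        if len(set(self.entry_ids)) != n:
            raise ValueError("duplicate entry ids")
        if len(set(self.marker_ids)) != p:
            raise ValueError("duplicate marker ids")
        # raw calls are 0/1/2; imputed cells may carry fractional means
        with np.errstate(invalid="ignore"):
            bad = ~(np.isnan(self.dosages)
                    | ((self.dosages >= 0.0) & (self.dosages <= 2.0)))
        if bad.any():
            raise ValueError("dosages must lie in [0, 2] or be missing")

    @property
    def n_entries(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Alternative-allele frequency per marker from non-missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.entry_ids, columns=self.marker_ids)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="entry")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MarkerMatrix":
        return cls(list(df.index), df.to_numpy(dtype=float), list(df.columns))


@dataclass
class QCReport:
    """Counts of markers dropped per quality-control rule."""

    n_input: int
    n_monomorphic: int
    n_low_maf: int
    n_high_missing: int
    n_retained: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class KinshipMatrix:
    """N x N genomic relationship matrix with entry labels.

    Symmetric, positive semidefinite up to numerical tolerance; rows sum to
    zero when built from column-centred dosages.  ``factor`` returns an
    N x r matrix L with L L' = K used to reparameterize kinship-structured
    random effects (handles singular K without inverting it).
    """

    entry_ids: list
    values: np.ndarray
    _factor_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.entry_ids = list(self.entry_ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.entry_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match entry labels")
        scale = max(np.abs(self.values).max(), 1.0)
        if np.abs(self.values - self.values.T).max() > 1e-8 * scale:
            raise ValueError("kinship matrix is not symmetric")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.entry_ids)

    def index_of(self, entries) -> np.ndarray:
        pos = {e: i for i, e in enumerate(self.entry_ids)}
        try:
            return np.array([pos[e] for e in entries], dtype=int)
        except KeyError as err:
            raise KeyError(f"entry {err.args[0]!r} not present in kinship matrix") from None

    def submatrix(self, entries) -> "KinshipMatrix":
        idx = self.index_of(entries)
        return KinshipMatrix(list(entries), self.values[np.ix_(idx, idx)])

    def factor(self, entries=None, tol: float = 1e-10) -> np.ndarray:
        """Return L (n x r) with L @ L.T == K (restricted to ``entries``).

        Eigenvalues below ``tol * lambda_max`` are treated as zero; an
        eigenvalue more negative than ``-100 * tol * lambda_max`` raises.
        Results are cached per entry subset.
        """
        key = None if entries is None else tuple(entries)
        if key in self._factor_cache:
            return self._factor_cache[key]
        if entries is None:
            vals = self.values
        else:
            idx = self.index_of(entries)
            vals = self.values[np.ix_(idx, idx)]
        w, u = np.linalg.eigh(vals)
        lam_max = max(w.max(), tol)
        if w.min() < -1e-8 * lam_max * 100:
            raise np.linalg.LinAlgError("kinship matrix has a substantially negative eigenvalue")
        keep = w > tol * lam_max
        L = u[:, keep] * np.sqrt(w[keep])
        self._factor_cache[key] = L
        return L

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.entry_ids, columns=self.entry_ids)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="entry")

    @classmethod
    def from_csv(cls, path) -> "KinshipMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if list(df.index) != list(df.columns):
            raise ValueError("kinship CSV row and column labels disagree")
        return cls(list(df.index), df.to_numpy(dtype=float))


def filter_markers(
    markers: MarkerMatrix,
    maf_min: float = 0.05,
    max_missing: float = 0.10,
) -> tuple[MarkerMatrix, QCReport]:
    """Drop monomorphic, low-MAF and poorly observed markers.

    A marker is dropped if (checked in this order, each marker counted once
    under the first rule that bites): its missing fraction exceeds
    ``max_missing``; it is monomorphic among non-missing calls; its minor
    allele frequency is below ``maf_min``.
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ValueError("maf_min must lie in [0, 0.5]")
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError("max_missing must lie in [0, 1]")

    miss = markers.missing_fraction()
    with np.errstate(invalid="ignore"):
        p = markers.allele_frequencies()
    maf = np.minimum(p, 1.0 - p)

    too_missing = miss > max_missing
    fully_missing = np.isnan(p)
    mono = (~too_missing) & (fully_missing | (maf == 0.0))
    low_maf = (~too_missing) & (~mono) & (maf < maf_min)
    keep = ~(too_missing | mono | low_maf)

    report = QCReport(
        n_input=markers.n_markers,
        n_monomorphic=int(mono.sum()),
        n_low_maf=int(low_maf.sum()),
        n_high_missing=int(too_missing.sum()),
        n_retained=int(keep.sum()),
    )
    if report.n_retained == 0:
        counts = {
            "missingness": report.n_high_missing,
            "monomorphic": report.n_monomorphic,
            "low MAF": report.n_low_maf,
        }
        binding = max(counts, key=counts.get)
        raise ValueError(f"all markers dropped by QC (dominant rule: {binding})")
    filtered = MarkerMatrix(
        markers.entry_ids,
        markers.dosages[:, keep],
        [m for m, k in zip(markers.marker_ids, keep) if k],
    )
    return filtered, report


def impute_missing(markers: MarkerMatrix) -> MarkerMatrix:
    """Replace missing calls by the marker's mean dosage 2*p_hat."""
    dos = markers.dosages.copy()
    nan_mask = np.isnan(dos)
    if not nan_mask.any():
        return MarkerMatrix(markers.entry_ids, dos, markers.marker_ids)
    if nan_mask.all(axis=0).any():
        raise ValueError("fully missing marker; run filter_markers first")
    col_mean = np.nanmean(dos, axis=0)
    dos[nan_mask] = np.broadcast_to(col_mean, dos.shape)[nan_mask]
    return MarkerMatrix(markers.entry_ids, dos, markers.marker_ids)


def vanraden_kinship(markers: MarkerMatrix) -> KinshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    K = Qc Qc' / c with Qc the dosage matrix centred by 2*p_hat per marker
    and c = 2 * sum_j p_hat_j (1 - p_hat_j).  Allele frequencies are
    computed from the analyzed entries themselves.
    """
    dos = markers.dosages
    if np.isnan(dos).any():
        raise ValueError("markers contain missing calls; impute first")
    p = dos.mean(axis=0) / 2.0
    c = 2.0 * np.sum(p * (1.0 - p))
    if c <= 0.0:
        raise ValueError("all markers are monomorphic; kinship scaling constant is zero")
    qc = dos - 2.0 * p
    k = (qc @ qc.T) / c
    return KinshipMatrix(markers.entry_ids, k)


def read_genotype_csv(path) -> MarkerMatrix:
    """Read an entries-in-rows genotype CSV/TSV (header = marker ids, NA missing)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, index_col=0, sep=sep)
    df.index = df.index.astype(str)
    return MarkerMatrix(list(df.index), df.to_numpy(dtype=float), list(df.columns))


def read_genotype_vcf(path) -> MarkerMatrix:
    """Read biallelic genotypes from a VCF into dosage codes (requires cyvcf2)."""
    try:
        from cyvcf2 import VCF
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError("reading VCF genotypes requires the cyvcf2 package") from err
    vcf = VCF(str(path))
    entries = list(vcf.samples)
    marker_ids: list[str] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        gts = np.asarray(var.genotype.array())[:, :2].astype(float)
        gts[gts < 0] = np.nan
        cols.append(gts.sum(axis=1))
    if not cols:
        raise ValueError("no biallelic variants found in VCF")
    return MarkerMatrix(entries, np.column_stack(cols), marker_ids)
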