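"""PCA of library-size-normalized, log-transformed junction coverage.

For counts ``c_ij`` (junction i, sample j) and per-sample mapped-read totals
``C_j``, the normalized log-coverage is ``x_ij = log2(c_ij / C_j + 1)`` —
zero counts map exactly to zero.  PCA operates on the row-centered matrix
``A_ij = x_ij − mean_j(x_ij)`` through its sample x sample Gram matrix
``AᵗA``, accumulated over row blocks so the junction dimension never has to
be densified at once; the right-singular vectors of ``A`` (eigenvectors of
``AᵗA``) are the principal components, one coordinate per sample.

Three per-sample correlates of the leading components are computed:
``s_j = Σ_i x_ij`` (junction sequencing depth after normalization),
``ℓ_j = log2(1 + p_j)`` (log read length) and ``m_j = log2(1 + C_j)``
(log mapped reads).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.linalg import eigh

from .classify import EvidenceCategory, category_array
from .model import JunctionTable, SampleMeta

__all__ = [
    "NormalizedMatrix",
    "PCAResult",
    "select_pca_input",
    "normalize",
    "gram_blockwise",
    "decompose",
    "correlate_components",
    "pca_pipeline",
]


def select_pca_input(
    t: JunctionTable,
    categories: Mapping[tuple, EvidenceCategory],
    meta: Sequence[SampleMeta],
    min_prevalence: int = 1000,
    min_reads: int = 100_000,
    unannotated: str = "not_fully",
) -> JunctionTable:
    """Restrict to unannotated junctions and sufficiently deep samples.

    Rows keep junctions with prevalence >= ``min_prevalence`` whose category
    is not fully annotated (``unannotated="not_fully"``, the default: partial
    evidence counts as unannotated) or strictly novel
    (``unannotated="novel"``).  Columns keep samples with mapped reads
    ``C_j >= min_reads``.
    """
    cats = category_array(t, categories)
    if unannotated == "not_fully":
        cat_mask = cats != int(EvidenceCategory.FULLY_ANNOTATED)
    elif unannotated == "novel":
        cat_mask = cats == int(EvidenceCategory.NOVEL)
    else:
        raise ValueError("unannotated must be 'not_fully' or 'novel'")
    prev_mask = t.sample_prevalence() >= min_prevalence
    jmask = cat_mask & prev_mask
    reads_by_id = {m.sample_id: m.mapped_reads for m in meta}
    smask = np.array(
        [(reads_by_id.get(s) or 0) >= min_reads for s in t.sample_ids]
    )
    if not jmask.any() or not smask.any():
        raise ValueError(
            "empty PCA input: "
            f"{int(cat_mask.sum())}/{t.n_junctions} unannotated, "
            f"{int(jmask.sum())} after prevalence >= {min_prevalence}, "
            f"{int(smask.sum())}/{t.n_samples} samples with C_j >= {min_reads}"
        )
    return t.subset(jmask, smask)


@dataclass
class NormalizedMatrix:
    """x = log2(c/C + 1) (sparse, zeros exact) and its row-centering data."""

    x: sp.csr_matrix
    row_means: np.ndarray
    sample_ids: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.x.shape

    def dense_centered(self) -> np.ndarray:
        """A = x − row means, densified (small inputs / tests only)."""
        return self.x.toarray() - self.row_means[:, None]


def normalize(t: JunctionTable, meta: Sequence[SampleMeta]) -> NormalizedMatrix:
    """Compute x_ij = log2(c_ij / C_j + 1) and row means for centering."""
    reads_by_id = {m.sample_id: m.mapped_reads for m in meta}
    C = np.array([reads_by_id.get(s) or 0 for s in t.sample_ids], dtype=np.float64)
    if (C <= 0).any():
        bad = [s for s, c in zip(t.sample_ids, C) if c <= 0]
        raise ValueError(f"samples with nonpositive mapped reads: {bad[:5]}")
    x = t.counts.tocoo().astype(np.float64)
    x.data = np.log2(x.data / C[x.col] + 1.0)
    x = x.tocsr()
    row_means = np.asarray(x.sum(axis=1)).ravel() / t.n_samples
    return NormalizedMatrix(x=x, row_means=row_means, sample_ids=list(t.sample_ids))


def gram_blockwise(nm: NormalizedMatrix, block_rows: int = 4096) -> np.ndarray:
    """Accumulate the sample x sample Gram matrix AᵗA over row blocks.

    Each block of x is densified, centered with its row means, and its
    contribution added; the result is independent of ``block_rows`` up to
    floating-point roundoff, symmetric and positive semidefinite.
    """
    if block_rows < 1:
        raise ValueError("block_rows must be >= 1")
    n_rows, n_samples = nm.shape
    gram = np.zeros((n_samples, n_samples))
    for lo in range(0, n_rows, block_rows):
        hi = min(lo + block_rows, n_rows)
        block = nm.x[lo:hi].toarray() - nm.row_means[lo:hi, None]
        gram += block.T @ block
    return 0.5 * (gram + gram.T)


@dataclass
class PCAResult:
    components: np.ndarray  # (n_samples, n_components); orthonormal columns
    singular_values: np.ndarray  # descending, >= 0
    variance_fraction: np.ndarray  # eigenvalue_k / trace(gram)
    sample_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def scores(self, scaled: bool = True) -> np.ndarray:
        """Per-sample coordinates; ``scaled`` multiplies by singular values
        (both scalings are legitimate plotting conventions and leave
        correlations unchanged)."""
        if scaled:
            return self.components * self.singular_values
        return self.components


def _orient(components: np.ndarray) -> np.ndarray:
    # deterministic sign: largest-|coordinate| entry of each PC positive
    out = components.copy()
    for k in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, k])))
        if out[i, k] < 0:
            out[:, k] = -out[:, k]
    return out


def decompose(
    gram: np.ndarray,
    n_components: int,
    sample_ids: Sequence[str],
    method: str = "exact",
    seed: int | None = None,
) -> PCAResult:
    """Eigendecompose AᵗA into principal components.

    ``exact`` uses a full symmetric eigendecomposition; ``randomized`` uses
    a seeded randomized SVD and matches the exact result to ~1e-6 on
    variance fractions for spectra with reasonable decay.  Singular values
    of A are square roots of the Gram eigenvalues; variance fractions are
    eigenvalues over trace(gram) (total variance), so they sum to 1 over a
    full decomposition.
    """
    n = gram.shape[0]
    if n_components > n:
        raise ValueError(f"n_components={n_components} exceeds dimension {n}")
    trace = float(np.trace(gram))
    if method == "exact":
        evals, evecs = eigh(gram)
        order = np.argsort(evals)[::-1][:n_components]
        evals, evecs = evals[order], evecs[:, order]
    elif method == "randomized":
        from sklearn.utils.extmath import randomized_svd

        u, s, _ = randomized_svd(
            gram, n_components=n_components, n_iter=7, random_state=seed
        )
        evals, evecs = s, u
    else:
        raise ValueError(f"method must be 'exact' or 'randomized', got {method!r}")
    evals = np.clip(evals, 0.0, None)
    return PCAResult(
        components=_orient(evecs),
        singular_values=np.sqrt(evals),
        variance_fraction=evals / trace if trace > 0 else np.zeros_like(evals),
        sample_ids=list(sample_ids),
    )


def correlate_components(
    res: PCAResult,
    nm: NormalizedMatrix,
    meta: Sequence[SampleMeta],
) -> "pd.DataFrame":
    """Pearson r of each component with depth/read-length/library correlates.

    ``s_j`` is computed from the UNcentered x.  A zero-variance correlate
    yields NaN (flagged in a ``defined`` column), never a spurious 0.
    The first component is re-oriented, here and in ``res``, so that
    r(PC1, s_j) >= 0 — a reproducible display convention that leaves
    magnitudes untouched.
    """
    import pandas as pd

    by_id = {m.sample_id: m for m in meta}
    missing = [s for s in res.sample_ids if s not in by_id]
    if missing:
        raise ValueError(f"metadata missing for samples: {missing[:5]}")
    s_j = np.asarray(nm.x.sum(axis=0)).ravel()
    ell = np.array(
        [np.log2(1 + (by_id[s].read_length or 0)) for s in res.sample_ids]
    )
    m_j = np.array(
        [np.log2(1 + (by_id[s].mapped_reads or 0)) for s in res.sample_ids]
    )
    correlates = {"s_depth": s_j, "l_read_length": ell, "m_mapped_reads": m_j}

    def _r(a: np.ndarray, b: np.ndarray) -> float:
        if np.std(a) == 0 or np.std(b) == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    r1 = _r(res.components[:, 0], s_j)
    if np.isfinite(r1) and r1 < 0:
        res.components[:, 0] = -res.components[:, 0]

    rows = []
    for name, vec in correlates.items():
        row = {"correlate": name, "defined": bool(np.std(vec) > 0)}
        for k in range(res.n_components):
            row[f"r_pc{k + 1}"] = _r(res.components[:, k], vec)
        rows.append(row)
    return pd.DataFrame(rows).set_index("correlate")


def pca_pipeline(
    t: JunctionTable,
    categories: Mapping[tuple, EvidenceCategory],
    meta: Sequence[SampleMeta],
    min_prevalence: int = 1000,
    min_reads: int = 100_000,
    n_components: int = 2,
    method: str = "exact",
    seed: int | None = None,
    block_rows: int = 4096,
) -> tuple[PCAResult, "pd.DataFrame", NormalizedMatrix]:
    """Filter, normalize, decompose and correlate in one call."""
    sub = select_pca_input(t, categories, meta, min_prevalence, min_reads)
    nm = normalize(sub, meta)
    gram = gram_blockwise(nm, block_rows)
    res = decompose(gram, n_components, nm.sample_ids, method=method, seed=seed)
    corr = correlate_components(res, nm, meta)
    return res, corr, nm
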