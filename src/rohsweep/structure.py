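"""Population stratification via genotype principal component analysis.

Standard genotype PCA: each SNP column is centered on twice its alt
frequency and scaled by sqrt(2p(1-p)), the binomial standard deviation
of the dosage under Hardy-Weinberg; missing calls are mean-imputed
(centered to zero) for the decomposition only.  Eigenvectors of the
sample covariance give per-sample coordinates; PC signs are fixed by
making each component's largest-magnitude SNP loading positive so runs
are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix
from .genotype_io import allele_frequencies

log = logging.getLogger(__name__)


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # sample_id, population, PC1..PCk
    explained_variance: np.ndarray  # fraction per component, non-increasing
    loadings: np.ndarray  # k x n_snps_used
    used_markers: np.ndarray  # indices of non-monomorphic markers used


def genotype_pca(g: GenotypeMatrix, k: int = 10) -> PcaResult:
    """Leading ``k`` principal components of the genotype matrix."""
    if k < 1 or k > min(g.n_samples, g.n_markers):
        raise ValueError("k must satisfy 1 <= k <= min(n_samples, n_markers)")
    freq = allele_frequencies(g.calls)
    poly = ~np.isnan(freq) & (freq > 0.0) & (freq < 1.0)
    n_dropped = int((~poly).sum())
    if n_dropped:
        log.info("genotype_pca: dropped %d monomorphic/empty markers", n_dropped)
    used = np.flatnonzero(poly)
    if used.size < k:
        raise ValueError("fewer polymorphic markers than requested components")
    x = g.calls[:, used].astype(float)
    p = freq[used]
    x[g.calls[:, used] == MISSING] = 2.0 * p[np.nonzero(g.calls[:, used] == MISSING)[1]]
    x -= 2.0 * p
    x /= np.sqrt(2.0 * p * (1.0 - p))

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigvals = s**2
    total = eigvals.sum()
    # sign convention: largest-|loading| entry of each PC positive
    for i in range(k):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    coords = u[:, :k] * s[:k]
    frame = pd.DataFrame({"sample_id": g.samples, "population": g.populations})
    for i in range(k):
        frame[f"PC{i + 1}"] = coords[:, i]
    explained = eigvals[:k] / total if total > 0 else np.zeros(k)
    return PcaResult(
        coordinates=frame,
        explained_variance=explained,
        loadings=vt[:k],
        used_markers=used,
    )


def write_eigenvec(result: PcaResult, path) -> None:
    """PLINK .eigenvec-style TSV: FID (population), IID, PC columns."""
    out = result.coordinates.rename(
        columns={"population": "FID", "sample_id": "IID"}
    )
    cols = ["FID", "IID"] + [c for c in out.columns if c.startswith("PC")]
    out[cols].to_csv(path, sep="\t", index=False)
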