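"""Species demultiplexing of mixed human/mouse droplets.

After alignment to a dual human-mouse reference, each cell's human-transcript
ratio r (human UMIs over total UMIs) is computed; cells are called human at
r >= 0.8, mouse at r <= 0.2, and Unknown in between — the band that captures
doublets and heavily contaminated droplets. The ratio histogram of a healthy
run is bimodal with peaks near 0 and 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import CountMatrix

DEFAULT_LO = 0.2
DEFAULT_HI = 0.8


@dataclass
class QCParams:
    """Cell-level quality-control floors applied before ratio computation."""

    min_genes: int = 200
    min_umis: int = 500

    def __post_init__(self) -> None:
        if self.min_genes < 0 or self.min_umis < 0:
            raise ValueError("QC thresholds must be nonnegative")


def human_ratio(matrix: CountMatrix, per_gene: bool = False) -> pd.Series:
    """Per-cell human-transcript ratio.

    r = (human-tagged UMIs) / (total UMIs). With ``per_gene=True`` the ratio
    is computed over detected genes instead of UMIs.
    """
    if matrix.species is None:
        raise ValueError("matrix has no species tags")
    human_rows = matrix.species == "human"
    if per_gene:
        nz = (matrix.counts > 0)
        human = np.asarray(nz[human_rows].sum(axis=0)).ravel()
        total = np.asarray(nz.sum(axis=0)).ravel()
    else:
        human = np.asarray(matrix.counts[human_rows].sum(axis=0)).ravel()
        total = matrix.total_umis()
    zero = total == 0
    if zero.any():
        bad = matrix.barcodes[zero][0]
        raise ValueError(
            f"cell {bad!r} has zero total UMIs; run QC filtering first"
        )
    return pd.Series(human / total, index=matrix.barcodes, name="human_ratio")


def classify_species(
    ratios: pd.Series, lo: float = DEFAULT_LO, hi: float = DEFAULT_HI
) -> pd.Series:
    """Call species per cell: human iff r >= hi, mouse iff r <= lo.

    Both thresholds are closed, so r == hi is human and r == lo is mouse;
    everything strictly between is "unknown".
    """
    if not 0 <= lo < hi <= 1:
        raise ValueError(f"need 0 <= lo < hi <= 1, got lo={lo}, hi={hi}")
    r = np.asarray(ratios, dtype=float)
    labels = np.where(r >= hi, "human", np.where(r <= lo, "mouse", "unknown"))
    return pd.Series(labels, index=ratios.index, name="label")


def species_calls(
    matrix: CountMatrix, lo: float = DEFAULT_LO, hi: float = DEFAULT_HI
) -> pd.DataFrame:
    """Convenience: ratios + labels + depths as one table."""
    r = human_ratio(matrix)
    return pd.DataFrame(
        {
            "barcode": matrix.barcodes,
            "total_umis": matrix.total_umis(),
            "human_ratio": r.to_numpy(),
            "label": classify_species(r, lo, hi).to_numpy(),
        }
    )


def ratio_bimodality(
    ratios: pd.Series | np.ndarray, n_bins: int = 50
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    """Histogram the ratios, locate peaks, and flag bimodality.

    The histogram over [0, 1] is smoothed with a 3-bin moving average; peaks
    are local maxima of the smoothed curve, and the distribution is flagged
    bimodal iff two peaks are separated by a trough strictly below both.

    Returns (bin edges, raw counts, peak positions as bin centers, flag).
    """
    r = np.asarray(ratios, dtype=float)
    if len(r) < 2:
        raise ValueError("need at least two cells")
    counts, edges = np.histogram(r, bins=n_bins, range=(0.0, 1.0))
    # 3-bin moving average with edge correction (2-bin window at the ends)
    smooth = np.convolve(counts, np.ones(3), mode="same") / np.convolve(
        np.ones(n_bins), np.ones(3), mode="same"
    )
    # local maxima with out-of-range treated as below everything
    padded = np.concatenate([[-1.0], smooth, [-1.0]])
    peak_bins = [
        i
        for i in range(len(smooth))
        if padded[i + 1] > padded[i] and padded[i + 1] >= padded[i + 2]
        and smooth[i] > 0
    ]
    centers = (edges[:-1] + edges[1:]) / 2.0
    peaks = [float(centers[i]) for i in peak_bins]
    bimodal = False
    for ai in range(len(peak_bins)):
        for bi in range(ai + 1, len(peak_bins)):
            a, b = peak_bins[ai], peak_bins[bi]
            trough = smooth[a + 1 : b].min() if b > a + 1 else np.inf
            if trough < smooth[a] and trough < smooth[b]:
                bimodal = True
    return edges, counts, peaks, bimodal


def qc_filter(
    matrix: CountMatrix, params: QCParams | None = None
) -> tuple[CountMatrix, dict]:
    """Drop cells below the gene/UMI floors; report removals per criterion."""
    params = params or QCParams()
    genes_pc = matrix.genes_per_cell()
    umis_pc = matrix.total_umis()
    fail_genes = genes_pc < params.min_genes
    fail_umis = umis_pc < params.min_umis
    keep = ~(fail_genes | fail_umis)
    report = {
        "n_input": matrix.n_cells,
        "n_fail_min_genes": int(fail_genes.sum()),
        "n_fail_min_umis": int(fail_umis.sum()),
        "n_removed": int((~keep).sum()),
        "n_kept": int(keep.sum()),
        "warning": "all cells removed" if not keep.any() else None,
    }
    return matrix.subset_cells(keep), report
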