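"""Sparse gene-by-cell count container with species tags and 10x-style MTX IO.

Dual-reference alignment of a xenograft sample yields one count matrix whose
feature IDs carry a genome prefix (``GRCh38_`` for human, ``mm10_`` for mouse
by default). :class:`CountMatrix` keeps that matrix genes x cells, resolves
each feature to a species, and carries optional per-cell sample labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

DEFAULT_PREFIXES = {"human": "GRCh38_", "mouse": "mm10_"}


@dataclass
class CountMatrix:
    """UMI counts, genes x cells.

    Parameters
    ----------
    counts
        Sparse nonnegative integer matrix, shape ``(n_genes, n_cells)``.
    genes
        Feature IDs, unique, length ``n_genes``.
    barcodes
        Cell barcodes, unique, length ``n_cells``.
    species
        Per-gene species tag, each ``"human"`` or ``"mouse"``. ``None`` for
        single-species matrices.
    samples
        Optional per-cell sample label (e.g. ``"PFC_4MPT"``).
    """

    counts: sp.csr_matrix
    genes: np.ndarray
    barcodes: np.ndarray
    species: np.ndarray | None = None
    samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.genes = np.asarray(self.genes, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("feature IDs must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        if self.species is not None:
            self.species = np.asarray(self.species, dtype=object)
            bad = set(self.species) - {"human", "mouse"}
            if bad:
                raise ValueError(f"unknown species tags: {sorted(bad)}")
        if self.samples is not None:
            self.samples = np.asarray(self.samples, dtype=object)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def total_umis(self) -> np.ndarray:
        """Per-cell total UMI counts."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        """Per-cell number of detected (nonzero) genes."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            counts=self.counts[:, idx],
            genes=self.genes,
            barcodes=self.barcodes[idx],
            species=self.species,
            samples=None if self.samples is None else self.samples[idx],
        )

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return CountMatrix(
            counts=self.counts[idx, :],
            genes=self.genes[idx],
            barcodes=self.barcodes,
            species=None if self.species is None else self.species[idx],
            samples=self.samples,
        )

    # ---------------------------------------------------------------- IO

    @classmethod
    def read_mtx_dir(
        cls,
        path: str | Path,
        prefixes: dict[str, str] | None = None,
        samples: pd.Series | None = None,
    ) -> "CountMatrix":
        """Read a 10x-style triplet (matrix.mtx, features.tsv, barcodes.tsv).

        ``prefixes`` maps species name -> feature-ID prefix; features matching
        no prefix leave ``species`` unset for the whole matrix only if no
        prefix map is given, otherwise raise.
        """
        path = Path(path)
        counts = sp.csr_matrix(scipy.io.mmread(path / "matrix.mtx"))
        features = pd.read_csv(path / "features.tsv", sep="\t", header=None)
        genes = features[0].to_numpy(dtype=object)
        barcodes = (
            pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0]
            .to_numpy(dtype=object)
        )
        species = None
        if prefixes is not None:
            species = tag_species(genes, prefixes)
        sample_arr = None
        if samples is not None:
            sample_arr = samples.reindex(barcodes).to_numpy(dtype=object)
        return cls(counts, genes, barcodes, species=species, samples=sample_arr)

    def write_mtx_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(
            str(path / "matrix.mtx"), sp.coo_matrix(self.counts), field="integer"
        )
        pd.DataFrame({"id": self.genes}).to_csv(
            path / "features.tsv", sep="\t", header=False, index=False
        )
        pd.DataFrame({"barcode": self.barcodes}).to_csv(
            path / "barcodes.tsv", sep="\t", header=False, index=False
        )


def tag_species(genes: np.ndarray, prefixes: dict[str, str] | None = None) -> np.ndarray:
    """Resolve each feature ID to a species via its genome prefix.

    Raises if any feature matches zero or more than one prefix.
    """
    prefixes = prefixes or DEFAULT_PREFIXES
    out = np.empty(len(genes), dtype=object)
    for i, g in enumerate(genes):
        hits = [spc for spc, pre in prefixes.items() if str(g).startswith(pre)]
        if len(hits) != 1:
            raise ValueError(
                f"feature {g!r} matches {len(hits)} species prefixes; "
                "every feature must resolve to exactly one species"
            )
        out[i] = hits[0]
    return out
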