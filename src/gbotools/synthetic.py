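"""Synthetic-data generators with known ground truth for every pipeline stage.

The study's raw data (mixed human/mouse droplet counts, grouped graft
transcriptomes, traced astrocyte skeletons, calcium movies) are replaced here
by generators that emulate the relevant statistical structure and return the
planted truth alongside, so every downstream operator can be scored without
any download:

* :func:`simulate_barnyard` — mixed-species droplet counts with ambient
  contamination and 50/50 doublets, producing the bimodal human-ratio
  distribution a dual-genome alignment shows.
* :func:`simulate_grouped_counts` — negative-binomial counts across the five
  sample groups (D0, PFC_2MPT, PFC_4MPT, HIP_2MPT, HIP_4MPT) with planted
  region- and time-specific log2 fold-change programs.
* :func:`simulate_reference_panel` — reference expression panels with a known
  sample-to-reference best-match map.
* :func:`simulate_skeleton` — SWC-style astrocyte skeletons with known branch
  statistics.
* :func:`simulate_trace` — stimulus-locked fluorescence traces with known
  onset and amplitude.
* :func:`simulate_neurite_points` — neurite point clouds covering a known
  fraction of a skeleton's length.

All generators are deterministic given their config (which includes a seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix import DEFAULT_PREFIXES, CountMatrix
from .morphometry import Skeleton
from .signals import TraceSet

# The five-group design of the study: pre-graft organoids (D0) and grafts
# into prefrontal cortex / hippocampus harvested 2 and 4 months
# post-transplantation.
DEFAULT_GROUPS = (
    ("D0", "none", 0),
    ("PFC_2MPT", "PFC", 2),
    ("PFC_4MPT", "PFC", 4),
    ("HIP_2MPT", "HIP", 2),
    ("HIP_4MPT", "HIP", 4),
)


# --------------------------------------------------------------------------
# barnyard droplets


@dataclass
class BarnyardConfig:
    """Mixed-species droplet simulation settings.

    ``ambient_fraction`` of each droplet's UMIs is replaced by draws from a
    pooled cross-species ambient profile (cell-free RNA); depth per cell is
    Poisson around ``mean_umis_per_cell``. Doublets contain both a human and
    a mouse cell at ~50/50 contribution.
    """

    n_human: int = 1000
    n_mouse: int = 1000
    n_doublets: int = 0
    ambient_fraction: float = 0.01
    mean_umis_per_cell: float = 5000.0
    n_genes_per_species: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_human, self.n_mouse, self.n_doublets) < 0:
            raise ValueError("cell counts must be nonnegative")
        if not 0 <= self.ambient_fraction < 1:
            raise ValueError("ambient_fraction must be in [0, 1)")
        if self.mean_umis_per_cell <= 0:
            raise ValueError("mean_umis_per_cell must be positive")
        if self.n_genes_per_species < 1:
            raise ValueError("need at least one gene per species")

    @property
    def ambient_human_share(self) -> float:
        """Human share of the pooled ambient profile.

        Ambient RNA is pooled from all loaded cells, so the human share is
        the human fraction of cellular material (doublets count half).
        """
        total = self.n_human + self.n_mouse + self.n_doublets
        return (self.n_human + 0.5 * self.n_doublets) / total


def simulate_barnyard(config: BarnyardConfig) -> tuple[CountMatrix, np.ndarray]:
    """Simulate a barnyard run; returns (matrix, true per-cell labels).

    Labels are ``"human"``, ``"mouse"`` or ``"doublet"``. Singlets draw UMIs
    from their own species' expression profile, then ``ambient_fraction`` of
    the UMIs is replaced by draws from the pooled ambient profile, keeping
    per-cell depth fixed — so the expected human ratio of a mouse singlet is
    exactly ``ambient_fraction * ambient_human_share``.
    """
    n_cells = config.n_human + config.n_mouse + config.n_doublets
    if n_cells == 0:
        raise ValueError("zero cells requested; nothing to simulate")
    rng = np.random.default_rng(config.seed)
    g = config.n_genes_per_species

    # per-species expression profiles over that species' genes
    human_profile = rng.dirichlet(np.full(g, 0.5))
    mouse_profile = rng.dirichlet(np.full(g, 0.5))
    share = config.ambient_human_share
    # ambient pool over all 2g genes: species profiles mixed by pool share
    ambient = np.concatenate([share * human_profile, (1 - share) * mouse_profile])
    human_full = np.concatenate([human_profile, np.zeros(g)])
    mouse_full = np.concatenate([np.zeros(g), mouse_profile])
    doublet_full = 0.5 * human_full + 0.5 * mouse_full

    labels = np.array(
        ["human"] * config.n_human
        + ["mouse"] * config.n_mouse
        + ["doublet"] * config.n_doublets,
        dtype=object,
    )
    profiles = {"human": human_full, "mouse": mouse_full, "doublet": doublet_full}

    depth = rng.poisson(config.mean_umis_per_cell, size=n_cells)
    depth = np.maximum(depth, 1)  # generated per-cell totals > 0

    cols = []
    for i in range(n_cells):
        total = int(depth[i])
        n_amb = rng.binomial(total, config.ambient_fraction)
        vec = rng.multinomial(total - n_amb, profiles[labels[i]])
        if n_amb:
            vec = vec + rng.multinomial(n_amb, ambient)
        cols.append(sp.csc_matrix(vec[:, None]))
    counts = sp.hstack(cols, format="csr")

    genes = np.array(
        [f"{DEFAULT_PREFIXES['human']}gene{j}" for j in range(g)]
        + [f"{DEFAULT_PREFIXES['mouse']}gene{j}" for j in range(g)],
        dtype=object,
    )
    species = np.array(["human"] * g + ["mouse"] * g, dtype=object)
    barcodes = np.array([f"CELL{i:06d}" for i in range(n_cells)], dtype=object)
    mat = CountMatrix(counts, genes, barcodes, species=species)
    return mat, labels


# --------------------------------------------------------------------------
# grouped negative-binomial counts with planted programs


@dataclass
class PlantedDesign:
    """Grouped count simulation with planted differential-expression programs.

    ``planted_region_genes`` maps gene name -> log2FC applied in PFC groups
    relative to HIP groups (positive = up in PFC). ``planted_time_genes``
    maps gene name -> log2FC applied proportionally to months post-graft
    (full effect at 4 months, half at 2, none at D0), so time structure is a
    monotone gradient. Counts are negative binomial with a shared dispersion
    ``nb_dispersion`` (variance = mu + dispersion * mu^2).
    """

    groups: tuple = DEFAULT_GROUPS
    n_cells_per_group: int = 100
    n_null_genes: int = 1000
    planted_region_genes: dict[str, float] = field(default_factory=dict)
    planted_time_genes: dict[str, float] = field(default_factory=dict)
    baseline_mean: float = 5.0
    nb_dispersion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.n_cells_per_group < 1:
            raise ValueError("need at least one cell per group")
        overlap = set(self.planted_region_genes) & set(self.planted_time_genes)
        if overlap:
            raise ValueError(f"genes planted on both axes: {sorted(overlap)}")
        for name, eff in {**self.planted_region_genes, **self.planted_time_genes}.items():
            if not math.isfinite(eff):
                raise ValueError(f"non-finite effect for {name}")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean mu, var mu + a*mu^2) via numpy's (n, p) parameterization."""
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_grouped_counts(design: PlantedDesign) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate the grouped design; returns (matrix, ground-truth DEG table).

    The truth table has columns ``gene``, ``axis`` (``region``/``time``) and
    ``effect`` (log2FC) and lists only genes with a nonzero planted effect.
    """
    rng = np.random.default_rng(design.seed)
    region_genes = list(design.planted_region_genes)
    time_genes = list(design.planted_time_genes)
    genes = (
        [f"null_gene{j}" for j in range(design.n_null_genes)] + region_genes + time_genes
    )
    if len(set(genes)) != len(genes):
        raise ValueError("planted gene names collide with null gene names")
    n_genes = len(genes)

    # per-gene baseline means scattered around the configured baseline
    base = design.baseline_mean * rng.lognormal(0.0, 0.3, size=n_genes)

    blocks, sample_labels = [], []
    for name, region, months in design.groups:
        mean = base.copy()
        for gi, gname in enumerate(genes):
            if gname in design.planted_region_genes and region != "none":
                eff = design.planted_region_genes[gname]
                # effect is log2(PFC/HIP); split symmetrically about baseline
                sign = 1.0 if region == "PFC" else -1.0
                mean[gi] *= 2.0 ** (sign * eff / 2.0)
            elif gname in design.planted_time_genes:
                eff = design.planted_time_genes[gname]
                mean[gi] *= 2.0 ** (eff * months / 4.0)
        block = _nb_draw(
            rng,
            np.broadcast_to(mean[:, None], (n_genes, design.n_cells_per_group)),
            design.nb_dispersion,
        )
        blocks.append(block)
        sample_labels.extend([name] * design.n_cells_per_group)

    counts = sp.csr_matrix(np.hstack(blocks))
    barcodes = np.array(
        [f"CELL{i:06d}" for i in range(counts.shape[1])], dtype=object
    )
    mat = CountMatrix(
        counts,
        np.array(genes, dtype=object),
        barcodes,
        samples=np.array(sample_labels, dtype=object),
    )
    rows = [
        {"gene": gname, "axis": "region", "effect": eff}
        for gname, eff in design.planted_region_genes.items()
        if eff != 0
    ] + [
        {"gene": gname, "axis": "time", "effect": eff}
        for gname, eff in design.planted_time_genes.items()
        if eff != 0
    ]
    truth = pd.DataFrame(rows, columns=["gene", "axis", "effect"])
    return mat, truth


# --------------------------------------------------------------------------
# reference panels


def simulate_reference_panel(
    n_refs: int,
    n_samples: int,
    noise_sd: float,
    seed: int = 0,
    n_genes: int = 500,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Simulate a reference panel and query samples with known best matches.

    Each sample profile is one reference column plus i.i.d. Gaussian noise.
    Returns (panel genes x refs, samples genes x samples, truth map
    sample -> reference).
    """
    if n_refs < 2:
        raise ValueError("need at least two references")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    genes = [f"gene{j}" for j in range(n_genes)]
    refs = [f"ref{j}" for j in range(n_refs)]
    panel = pd.DataFrame(
        rng.lognormal(2.0, 1.0, size=(n_genes, n_refs)), index=genes, columns=refs
    )
    source = [refs[i % n_refs] for i in range(n_samples)]
    samp_names = [f"sample{j}" for j in range(n_samples)]
    profiles = panel[source].to_numpy() + rng.normal(0, noise_sd, (n_genes, n_samples))
    samples = pd.DataFrame(profiles, index=genes, columns=samp_names)
    truth = dict(zip(samp_names, source))
    return panel, samples, truth


# --------------------------------------------------------------------------
# skeletons


@dataclass
class SkeletonConfig:
    """Astrocyte skeleton generator settings.

    Each of ``n_primary`` branches leaves the soma and bifurcates at every
    level; ``branching_depth`` is the number of segment levels along each
    root-to-tip path (depth 1 = unbranched primary segment, so each primary
    carries ``2**(branching_depth-1)`` terminal tips). Segment endpoints get
    isotropic Gaussian positional jitter of scale ``jitter``.
    """

    n_primary: int = 4
    branching_depth: int = 3
    segment_length: float = 15.0
    jitter: float = 1.0
    soma_radius: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_primary < 1:
            raise ValueError("n_primary must be >= 1")
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")
        if self.branching_depth < 1:
            raise ValueError("branching_depth must be >= 1")


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def simulate_skeleton(config: SkeletonConfig) -> tuple[Skeleton, dict]:
    """Simulate a rooted skeleton; returns (skeleton, ground-truth stats).

    Truth records ``total_length`` (sum of parent-child Euclidean distances,
    accumulated edge by edge during construction), ``n_primary`` and
    ``n_terminal``.
    """
    rng = np.random.default_rng(config.seed)
    xyz = [np.zeros(3)]
    radius = [config.soma_radius]
    parent = [-1]
    ntype = [1]
    total_length = 0.0
    n_terminal = 0

    def grow(parent_idx: int, direction: np.ndarray, depth_left: int) -> None:
        nonlocal total_length, n_terminal
        end = xyz[parent_idx] + direction * config.segment_length
        if config.jitter > 0:
            end = end + rng.normal(0, config.jitter, 3)
        xyz.append(end)
        radius.append(0.5)
        parent.append(parent_idx)
        ntype.append(3)
        idx = len(xyz) - 1
        total_length += float(np.linalg.norm(end - xyz[parent_idx]))
        if depth_left == 1:
            n_terminal += 1
            return
        for _ in range(2):
            # child directions deviate from the parent's heading
            d = direction + 0.8 * _unit(rng)
            grow(idx, d / np.linalg.norm(d), depth_left - 1)

    for _ in range(config.n_primary):
        grow(0, _unit(rng), config.branching_depth)

    skel = Skeleton(
        ids=np.arange(1, len(xyz) + 1),
        types=np.array(ntype),
        xyz=np.array(xyz),
        radius=np.array(radius),
        parent_idx=np.array(parent),
    )
    truth = {
        "total_length": total_length,
        "n_primary": config.n_primary,
        "n_terminal": n_terminal,
        "soma_area": math.pi * config.soma_radius**2,
    }
    return skel, truth


# --------------------------------------------------------------------------
# calcium traces


@dataclass
class TraceConfig:
    """Stimulus-locked fluorescence trace settings.

    The noiseless trace sits at ``baseline_f`` until ``stimulus_time``, ramps
    linearly over ``rise_time`` to ``baseline_f * (1 + amplitude_fraction)``
    and stays there; ``rise_time = 0`` gives an instantaneous step. Gaussian
    noise of scale ``noise_sd`` is added pointwise.
    """

    dt: float = 0.1
    duration: float = 60.0
    stimulus_time: float = 10.0
    baseline_f: float = 100.0
    amplitude_fraction: float = 0.5
    rise_time: float = 2.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.stimulus_time < self.duration:
            raise ValueError("stimulus_time must lie inside the record")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.baseline_f <= 0:
            raise ValueError("baseline_f must be positive")
        if self.rise_time < 0 or self.noise_sd < 0:
            raise ValueError("rise_time and noise_sd must be nonnegative")


def simulate_trace(
    config: TraceConfig, n_cells: int = 1, group: str = "CONT"
) -> TraceSet:
    """Simulate ``n_cells`` traces from one config; returns a TraceSet."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(config.seed)
    times = np.arange(0.0, config.duration, config.dt)
    peak = config.baseline_f * (1.0 + config.amplitude_fraction)
    if config.rise_time > 0:
        frac = np.clip((times - config.stimulus_time) / config.rise_time, 0.0, 1.0)
    else:
        frac = (times > config.stimulus_time).astype(float)
    clean = config.baseline_f + frac * (peak - config.baseline_f)
    F = np.tile(clean, (n_cells, 1))
    if config.noise_sd > 0:
        F = F + rng.normal(0, config.noise_sd, F.shape)
    return TraceSet(
        times=times,
        F=F,
        stimulus_time=config.stimulus_time,
        cells=np.array([f"cell{i}" for i in range(n_cells)], dtype=object),
        groups=np.array([group] * n_cells, dtype=object),
    )


# --------------------------------------------------------------------------
# neurite point clouds


def simulate_neurite_points(
    skeleton: Skeleton,
    coverage_fraction: float,
    offset: float = 0.0,
    seed: int = 0,
    spacing: float = 0.2,
) -> tuple[np.ndarray, float]:
    """Place neurite evidence points along a known fraction of the skeleton.

    Edges are taken in a seeded random order and covered until
    ``coverage_fraction`` of total length is reached (the last edge covered
    partially from its parent end). Points are laid at ``spacing`` µm along
    covered stretches and displaced by a random vector of norm <= ``offset``.

    Returns (points ``(n, 3)``, true covered fraction).
    """
    if not 0 <= coverage_fraction <= 1:
        raise ValueError("coverage_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = skeleton.edges()
    if len(edges) == 0:
        raise ValueError("skeleton has no segments")
    lengths = np.array(
        [np.linalg.norm(skeleton.xyz[c] - skeleton.xyz[p]) for c, p in edges]
    )
    total = lengths.sum()
    target = coverage_fraction * total
    order = rng.permutation(len(edges))
    pts: list[np.ndarray] = []
    covered = 0.0
    for ei in order:
        if covered >= target:
            break
        c, p = edges[ei]
        a, b = skeleton.xyz[p], skeleton.xyz[c]
        take = min(lengths[ei], target - covered)
        if take <= 0:
            break
        n_pts = max(int(np.ceil(take / spacing)) + 1, 2)
        ts = np.linspace(0.0, take / lengths[ei], n_pts)
        seg_pts = a[None, :] + ts[:, None] * (b - a)[None, :]
        if offset > 0:
            disp = rng.normal(size=seg_pts.shape)
            disp /= np.linalg.norm(disp, axis=1, keepdims=True)
            disp *= offset * rng.uniform(0, 1, (len(seg_pts), 1))
            seg_pts = seg_pts + disp
        pts.append(seg_pts)
        covered += take
    points = np.vstack(pts) if pts else np.empty((0, 3))
    return points, covered / total
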