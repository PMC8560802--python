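"""Synthetic Visium-like and single-cell/nucleus data with planted truth.

The generator emulates the statistical structure the downstream tests
assume: a square lattice of capture spots partitioned into a central
tumor disc, an annular interface band where tumor contacts muscle, and
surrounding muscle; overdispersed (negative-binomial) counts; disjoint
marker-gene blocks per region; an interface expression program (cilia-like
genes up, ETS-like transcription-factor genes down) shared by tumor-like
and muscle-like interface cells; and higher per-spot UMI totals inside the
tumor.  Matched cell and nucleus datasets carry the same planted interface
states, with nucleus counts globally scaled down to mimic the lower mRNA
content of nuclei.

All generators are pure functions of (config, seed): the same inputs give
bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .datatypes import CellDataset, GeneSetCollection, SpotDataset

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_spatial",
    "generate_cells",
    "generate_gene_sets",
]

CELL_STATES = (
    "tumor",
    "muscle",
    "immune",
    "interface_tumor_like",
    "interface_muscle_like",
)

#: fraction of cells per planted state in generated cell/nucleus datasets
DEFAULT_STATE_PROPORTIONS = {
    "tumor": 0.30,
    "muscle": 0.20,
    "immune": 0.14,
    "interface_tumor_like": 0.18,
    "interface_muscle_like": 0.18,
}


class ConfigurationError(ValueError):
    """Raised when a SynthConfig violates its invariants."""


@dataclass
class SynthConfig:
    """Parameters of the synthetic tumor/interface/muscle world.

    Geometry: spots sit on a ``grid_rows x grid_cols`` square lattice with
    center-to-center distance ``spot_pitch`` (µm; Visium's 55 µm spots with
    a 45 µm gap give a 100 µm pitch).  A spot is *tumor* if its center lies
    within ``tumor_radius`` of ``tumor_center``, *interface* if within
    ``tumor_radius + interface_width``, else *muscle*.

    Expression: baseline per-gene means are lognormal, scaled so a baseline
    spot totals ``baseline_umi`` expected UMIs; counts are negative binomial
    with shape ``nb_dispersion`` (variance mu + mu^2/dispersion).  Region
    marker genes have their mean multiplied by ``2**effect_log2fc`` inside
    their region; interface-program genes likewise in interface spots/cells;
    ETS-like genes are divided by the same factor there.  Tumor spots are
    rescaled so their expected total is ``tumor_umi_multiplier`` x baseline.

    ``ets_anticorr`` sets the latent correlation between per-cell ETS and
    ETS-target activity inside interface cells (see ``generate_cells``).
    """

    grid_rows: int = 30
    grid_cols: int = 30
    spot_pitch: float = 100.0
    tumor_center: tuple[float, float] | None = None  # (row, col); grid center if None
    tumor_radius: float = 800.0
    interface_width: float = 300.0
    n_genes: int = 1000
    n_markers_per_region: int = 50
    n_interface_program_genes: int = 60
    n_ets_genes: int = 25
    n_ets_target_genes: int = 50
    n_mito_genes: int = 10
    mito_expression_fraction: float = 0.05
    nb_dispersion: float = 2.0
    tumor_umi_multiplier: float = 2.0
    effect_log2fc: float = 1.0
    ets_anticorr: float = -0.6
    ets_latent_log2_sd: float = 1.5
    baseline_umi: float = 4000.0
    n_cells: int = 3000
    nucleus_scale: float = 0.2
    state_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATE_PROPORTIONS)
    )
    seed: int = 0

    def __post_init__(self):
        if self.tumor_center is None:
            self.tumor_center = ((self.grid_rows - 1) / 2.0, (self.grid_cols - 1) / 2.0)
        for name in (
            "grid_rows",
            "grid_cols",
            "n_genes",
            "n_markers_per_region",
            "n_interface_program_genes",
            "n_ets_genes",
            "n_ets_target_genes",
            "n_cells",
        ):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.tumor_umi_multiplier < 1:
            raise ConfigurationError("tumor_umi_multiplier must be >= 1")
        if self.effect_log2fc < 0:
            raise ConfigurationError("effect_log2fc must be >= 0")
        if not (-1.0 <= self.ets_anticorr <= 0.0):
            raise ConfigurationError("ets_anticorr must lie in [-1, 0]")
        half_extent = (min(self.grid_rows, self.grid_cols) - 1) / 2.0 * self.spot_pitch
        if self.tumor_radius + self.interface_width >= half_extent:
            raise ConfigurationError(
                "tumor_radius + interface_width must be smaller than the grid "
                f"half-extent ({half_extent:g} µm)"
            )
        n_special = (
            3 * self.n_markers_per_region
            + self.n_interface_program_genes
            + self.n_ets_genes
            + self.n_ets_target_genes
            + self.n_mito_genes
        )
        if n_special > self.n_genes:
            raise ConfigurationError(
                f"n_genes={self.n_genes} too small for the requested disjoint "
                f"gene blocks ({n_special} genes)"
            )
        props = self.state_proportions
        if set(props) != set(CELL_STATES):
            raise ConfigurationError(f"state_proportions must cover {CELL_STATES}")
        if abs(sum(props.values()) - 1.0) > 1e-8:
            raise ConfigurationError("state_proportions must sum to 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted structure emitted alongside every synthetic dataset."""

    genes: list[str]
    region_of_spot: dict[str, str] = field(default_factory=dict)
    state_of_cell: dict[str, str] = field(default_factory=dict)
    marker_genes: dict[str, list[str]] = field(default_factory=dict)
    interface_program: list[str] = field(default_factory=list)
    ets_genes: list[str] = field(default_factory=list)
    ets_targets: list[str] = field(default_factory=list)
    planted_log2fc: dict[str, float] = field(default_factory=dict)
    ets_latent: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        blocks = list(self.marker_genes.values()) + [
            self.interface_program,
            self.ets_genes,
            self.ets_targets,
        ]
        seen: set[str] = set()
        for block in blocks:
            b = set(block)
            if b & seen:
                raise ValueError("planted gene blocks must be disjoint")
            seen |= b


# ---------------------------------------------------------------------------
# gene layout


def _gene_layout(config: SynthConfig) -> dict:
    """Deterministic assignment of gene names to planted blocks."""
    m = config.n_markers_per_region
    names: list[str] = []
    blocks: dict[str, list[str]] = {}

    def block(prefix: str, n: int) -> list[str]:
        genes = [f"{prefix}{i:04d}" for i in range(n)]
        names.extend(genes)
        return genes

    blocks["tumor"] = block("tum", m)
    blocks["muscle"] = block("mus", m)
    blocks["immune"] = block("imm", m)
    program = block("cil", config.n_interface_program_genes)
    # two program members carry ribosomal-style names so ribosome-filtering
    # rules downstream have planted positives to act on
    if len(program) >= 4:
        for i, ribo_name in ((0, "rps-cil0000"), (1, "rpl-cil0001")):
            names[names.index(program[i])] = ribo_name
            program[i] = ribo_name
    blocks["interface_program"] = program
    blocks["ets"] = block("ets", config.n_ets_genes)
    blocks["ets_target"] = block("tgt", config.n_ets_target_genes)
    blocks["mito"] = block("mt-", config.n_mito_genes)
    n_bg = config.n_genes - len(names)
    blocks["background"] = block("bg", n_bg)
    return {"gene_ids": names, "blocks": blocks}


def _baseline_means(config: SynthConfig, rng: np.random.Generator, layout: dict) -> np.ndarray:
    """Lognormal baseline means scaled so a spot totals baseline_umi UMIs,
    with the mito block pinned to a fixed fraction of total expression.

    Planted blocks (markers, interface program, ETS, ETS targets) have
    their raw lognormal means floored at the lognormal median: curated
    marker genes are by construction detectably expressed, and an
    unmeasurably rare 'marker' would make its planted effect unrecoverable
    at any sample size.
    """
    n = config.n_genes
    mu = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    gene_pos = {g: i for i, g in enumerate(layout["gene_ids"])}
    planted_idx = np.array(
        [
            gene_pos[g]
            for b in ("tumor", "muscle", "immune", "interface_program", "ets", "ets_target")
            for g in layout["blocks"][b]
        ],
        dtype=int,
    )
    mu[planted_idx] = np.maximum(mu[planted_idx], 1.0)  # lognormal(0,1) median
    mito_idx = [layout["gene_ids"].index(g) for g in layout["blocks"]["mito"]]
    mito_idx = np.array(mito_idx, dtype=int)
    non_mito = np.setdiff1d(np.arange(n), mito_idx)
    f = config.mito_expression_fraction
    mu[non_mito] *= (1.0 - f) * config.baseline_umi / mu[non_mito].sum()
    mu[mito_idx] *= f * config.baseline_umi / mu[mito_idx].sum()
    return mu


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + mu^2/dispersion, elementwise."""
    mean = np.asarray(mean, dtype=float)
    p = dispersion / (dispersion + mean)
    # numpy's parameterization: number of successes n, success prob p
    return rng.negative_binomial(dispersion, np.clip(p, 1e-12, 1.0))


def _ensure_no_zero_rows(counts: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Add one count to the highest-mean gene of any all-zero observation."""
    zero_rows = np.flatnonzero(counts.sum(axis=1) == 0)
    for i in zero_rows:
        counts[i, int(np.argmax(means[i]))] = 1
    return counts


def _stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent RNG stream derived from a base seed and a stream name."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(stream.encode())])


# ---------------------------------------------------------------------------
# spatial dataset


def generate_spatial(config: SynthConfig) -> tuple[SpotDataset, GroundTruth]:
    """Generate a Visium-like spot dataset with planted regions.

    Regions are assigned purely by geometry (distance of the spot center to
    the tumor center); counts are negative binomial with region-specific
    gene means.  The expected UMI total of each tumor spot is exactly
    ``tumor_umi_multiplier x baseline_umi``; interface and muscle spots
    total ``baseline_umi``.
    """
    rng = _stream_rng(config.seed, "spatial")
    layout = _gene_layout(config)
    gene_ids = layout["gene_ids"]
    blocks = layout["blocks"]
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    rows, cols = np.meshgrid(
        np.arange(config.grid_rows), np.arange(config.grid_cols), indexing="ij"
    )
    rows = rows.ravel()
    cols = cols.ravel()
    coords = np.column_stack([cols * config.spot_pitch, rows * config.spot_pitch])
    cr, cc = config.tumor_center
    center_xy = np.array([cc * config.spot_pitch, cr * config.spot_pitch])
    dist = np.hypot(coords[:, 0] - center_xy[0], coords[:, 1] - center_xy[1])

    region = np.where(
        dist <= config.tumor_radius,
        "tumor",
        np.where(dist <= config.tumor_radius + config.interface_width, "interface", "muscle"),
    ).astype(object)

    base = _baseline_means(config, rng, layout)
    eff = 2.0 ** config.effect_log2fc
    region_means = {r: base.copy() for r in ("tumor", "interface", "muscle")}
    for r in ("tumor", "muscle"):
        idx = [gene_pos[g] for g in blocks[r]]
        region_means[r][idx] *= eff
    ip_idx = [gene_pos[g] for g in blocks["interface_program"]]
    region_means["interface"][ip_idx] *= eff
    ets_idx = [gene_pos[g] for g in blocks["ets"]]
    region_means["interface"][ets_idx] /= eff

    # renormalize each region's expected spot total to its UMI target
    for r, means in region_means.items():
        target = config.baseline_umi * (
            config.tumor_umi_multiplier if r == "tumor" else 1.0
        )
        means *= target / means.sum()

    n_spots = len(region)
    mean_matrix = np.empty((n_spots, config.n_genes))
    for r, means in region_means.items():
        mean_matrix[region == r] = means
    counts = _nb_sample(rng, mean_matrix, config.nb_dispersion)
    counts = _ensure_no_zero_rows(counts, mean_matrix)

    spot_ids = np.array(
        [f"spot_r{r:03d}_c{c:03d}" for r, c in zip(rows, cols)], dtype=object
    )
    dataset = SpotDataset(
        counts=counts,
        coords=coords,
        spot_ids=spot_ids,
        gene_ids=np.array(gene_ids, dtype=object),
        cluster_of_spot=region,
    )
    planted = {g: config.effect_log2fc for b in ("tumor", "muscle") for g in blocks[b]}
    planted.update({g: config.effect_log2fc for g in blocks["interface_program"]})
    planted.update({g: -config.effect_log2fc for g in blocks["ets"]})
    truth = GroundTruth(
        genes=list(gene_ids),
        region_of_spot=dict(zip(spot_ids, region)),
        marker_genes={
            "tumor": list(blocks["tumor"]),
            "muscle": list(blocks["muscle"]),
            "immune": list(blocks["immune"]),
        },
        interface_program=list(blocks["interface_program"]),
        ets_genes=list(blocks["ets"]),
        ets_targets=list(blocks["ets_target"]),
        planted_log2fc=planted,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# cell / nucleus datasets


def generate_cells(
    config: SynthConfig, modality: str = "cell"
) -> tuple[CellDataset, GroundTruth]:
    """Generate a matched cell or nucleus dataset with planted states.

    States: tumor, muscle, immune, interface_tumor_like and
    interface_muscle_like.  Both interface states share elevated
    interface-program expression and depressed ETS expression; the
    tumor-like state co-expresses tumor markers and the muscle-like state
    muscle markers.  Inside interface cells, per-cell ETS and ETS-target
    activities follow a bivariate Gaussian latent factor with correlation
    ``ets_anticorr``: cell i multiplies its ETS gene means by
    ``2**(sd * z1_i)`` and its ETS-target means by ``2**(sd * z2_i)``.

    ``modality='nucleus'`` scales all gene means by ``nucleus_scale``
    (default 0.2), emulating the globally lower transcript recovery of
    single-nucleus data.
    """
    if modality not in ("cell", "nucleus"):
        raise ConfigurationError("modality must be 'cell' or 'nucleus'")
    rng = _stream_rng(config.seed, f"cells:{modality}")
    layout = _gene_layout(config)
    gene_ids = layout["gene_ids"]
    blocks = layout["blocks"]
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    base = _baseline_means(config, rng, layout)
    if modality == "nucleus":
        base = base * config.nucleus_scale
    eff = 2.0 ** config.effect_log2fc

    state_means = {}
    for state in CELL_STATES:
        mu = base.copy()
        if state in ("tumor", "interface_tumor_like"):
            mu[[gene_pos[g] for g in blocks["tumor"]]] *= eff
        if state in ("muscle", "interface_muscle_like"):
            mu[[gene_pos[g] for g in blocks["muscle"]]] *= eff
        if state == "immune":
            mu[[gene_pos[g] for g in blocks["immune"]]] *= eff
        if state.startswith("interface"):
            mu[[gene_pos[g] for g in blocks["interface_program"]]] *= eff
            mu[[gene_pos[g] for g in blocks["ets"]]] /= eff
        state_means[state] = mu

    # deterministic state assignment: largest-remainder apportionment
    counts_per_state = _apportion(config.n_cells, config.state_proportions)
    states = np.concatenate(
        [np.repeat(s, k) for s, k in counts_per_state.items()]
    ).astype(object)

    n = len(states)
    mean_matrix = np.empty((n, config.n_genes))
    for s in CELL_STATES:
        mean_matrix[states == s] = state_means[s]

    # bivariate latent factor for ETS anti-correlation in interface cells
    ets_idx = np.array([gene_pos[g] for g in blocks["ets"]])
    tgt_idx = np.array([gene_pos[g] for g in blocks["ets_target"]])
    iface = np.flatnonzero(
        (states == "interface_tumor_like") | (states == "interface_muscle_like")
    )
    a = config.ets_anticorr
    z1 = rng.standard_normal(len(iface))
    z2 = a * z1 + np.sqrt(max(0.0, 1.0 - a * a)) * rng.standard_normal(len(iface))
    sd = config.ets_latent_log2_sd
    mean_matrix[np.ix_(iface, ets_idx)] *= 2.0 ** (sd * z1)[:, None]
    mean_matrix[np.ix_(iface, tgt_idx)] *= 2.0 ** (sd * z2)[:, None]

    counts = _nb_sample(rng, mean_matrix, config.nb_dispersion)
    counts = _ensure_no_zero_rows(counts, mean_matrix)

    prefix = "nuc" if modality == "nucleus" else "cell"
    cell_ids = np.array([f"{prefix}_{i:05d}" for i in range(n)], dtype=object)
    mito_flags = np.array([g.startswith("mt-") for g in gene_ids])
    dataset = CellDataset(
        counts=counts,
        cell_ids=cell_ids,
        gene_ids=np.array(gene_ids, dtype=object),
        cluster_of_cell=states,
        modality=modality,
        mito_gene_flags=mito_flags,
    )
    planted = {g: config.effect_log2fc for b in ("tumor", "muscle", "immune") for g in blocks[b]}
    planted.update({g: config.effect_log2fc for g in blocks["interface_program"]})
    planted.update({g: -config.effect_log2fc for g in blocks["ets"]})
    truth = GroundTruth(
        genes=list(gene_ids),
        state_of_cell=dict(zip(cell_ids, states)),
        marker_genes={
            "tumor": list(blocks["tumor"]),
            "muscle": list(blocks["muscle"]),
            "immune": list(blocks["immune"]),
        },
        interface_program=list(blocks["interface_program"]),
        ets_genes=list(blocks["ets"]),
        ets_targets=list(blocks["ets_target"]),
        planted_log2fc=planted,
        ets_latent={
            str(cell_ids[i]): (float(z1[j]), float(z2[j]))
            for j, i in enumerate(iface)
        },
    )
    return dataset, truth


def _apportion(total: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder rounding of total into integer state counts."""
    raw = {s: total * p for s, p in proportions.items()}
    floored = {s: int(np.floor(v)) for s, v in raw.items()}
    remainder = total - sum(floored.values())
    order = sorted(raw, key=lambda s: (raw[s] - floored[s], s), reverse=True)
    for s in order[:remainder]:
        floored[s] += 1
    return {s: floored[s] for s in CELL_STATES}


# ---------------------------------------------------------------------------
# gene sets


def generate_gene_sets(
    truth: GroundTruth, n_random_sets: int, set_size: int, seed: int
) -> GeneSetCollection:
    """Gene-set collection with planted coherent sets plus random sets.

    Coherent sets (``COHERENT:<state>``) are drawn from the planted marker
    lists; ``CILIA_LIKE`` is the planted interface program; random sets
    (``RANDOM:<i>``) are uniform draws from the universe.
    """
    universe = list(truth.genes)
    if set_size > len(universe):
        raise ValueError("set_size exceeds the gene universe")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(b"gene_sets")])
    sets: dict[str, list[str]] = {}
    for state, markers in truth.marker_genes.items():
        take = min(set_size, len(markers))
        sets[f"COHERENT:{state}"] = list(markers[:take])
    sets["CILIA_LIKE"] = list(truth.interface_program)
    for i in range(n_random_sets):
        pick = rng.choice(len(universe), size=set_size, replace=False)
        sets[f"RANDOM:{i:04d}"] = [universe[j] for j in sorted(pick)]
    return GeneSetCollection(
        sets=sets, universe=universe, provenance="interface_atlas.synthio"
    )
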