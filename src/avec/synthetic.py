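"""Ground-truthed synthetic scRNA-seq generators.

Counts are drawn from a negative-binomial (gamma–Poisson) model: gene ``g``
in cell ``c`` has mean ``mu = p_g * 2**lfc_gc * L_c`` where ``p_g`` is a
baseline relative abundance, ``lfc_gc`` the planted log2 fold-change of the
cell's cluster program (plus any latent-time or cell-cycle modulation) and
``L_c`` a log-normal library size.  The generators emulate the population
structure every downstream stage assumes — discrete endothelial clusters
with arterial/venous marker programs, a continuous latent order within
designated clusters, a paired mural-cell compartment with planted
ligand–receptor pairs, and two species linked by a homolog map with planted
conserved markers — and return the ground truth alongside the data.  Ground
truth is consumed only by tests and scoring scripts, never by the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, ValidationError, normalize
from .signatures import load_signature

__all__ = [
    "ClusterProgram",
    "SyntheticSpec",
    "GroundTruth",
    "default_vec_spec",
    "continuum_spec",
    "null_spec",
    "two_species_spec",
    "mc_vec_spec",
    "generate_vec_dataset",
    "generate_two_species",
    "generate_mc_vec_pair",
    "generate_null_dataset",
]

_LIB_SIGMA = 0.3  # log-sd of the log-normal library sizes
_MARKER_WEIGHT = 3.0  # baseline relative abundance of marker/program genes


@dataclass
class ClusterProgram:
    """A named cluster with its cell fraction and marker program
    (gene -> planted log2 fold-change relative to baseline)."""

    name: str
    fraction: float
    program: dict[str, float] = field(default_factory=dict)


@dataclass
class SyntheticSpec:
    """Full description of a synthetic dataset; identical spec+seed give
    identical output."""

    n_genes: int
    n_cells: int
    cluster_profile: list[ClusterProgram]
    latent_time_clusters: list[str] = field(default_factory=list)
    marker_sets: dict[str, list[str]] = field(default_factory=dict)
    library_size_mean: float = 100_000.0
    dispersion: float = 0.05
    batch_count: int = 2
    flip_fraction: float = 0.0
    temporal_log2fc: float = 2.0
    cc_log2fc: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        total = sum(c.fraction for c in self.cluster_profile)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"cluster_profile: cell fractions sum to {total}, not 1"
            )
        names = [c.name for c in self.cluster_profile]
        if len(set(names)) != len(names):
            raise ValidationError("cluster_profile: duplicate cluster names")
        for c in self.cluster_profile:
            for gene, lfc in c.program.items():
                if not np.isfinite(lfc):
                    raise ValidationError(
                        f"cluster_profile: non-finite fold-change for {gene!r}"
                    )
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        if not 0 <= self.flip_fraction < 1:
            raise ValidationError("flip_fraction must be in [0, 1)")
        if self.batch_count < 1:
            raise ValidationError("batch_count must be >= 1")
        unknown = set(self.latent_time_clusters) - set(names)
        if unknown:
            raise ValidationError(f"latent_time_clusters: unknown clusters {unknown}")

    # -- serialization ("structured config file") ------------------------------

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticSpec":
        raw = json.loads(Path(path).read_text())
        raw["cluster_profile"] = [ClusterProgram(**c) for c in raw["cluster_profile"]]
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted truth: per-cell labels/latent time, per-contrast DE genes,
    planted interaction pairs and conserved genes."""

    cells: pd.DataFrame
    de_genes: dict[str, set[str]] = field(default_factory=dict)
    temporal_genes: list[str] = field(default_factory=list)
    flipped_cells: list[str] = field(default_factory=list)
    planted_pairs: list[tuple[str, str]] = field(default_factory=list)
    decoy_pairs: list[tuple[str, str]] = field(default_factory=list)
    conserved_genes: dict[str, set[str]] = field(default_factory=dict)
    species_specific: dict[str, set[str]] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        self.cells.to_csv(path, sep="\t")


# -- core generator ------------------------------------------------------------


def _gene_namespace(spec: SyntheticSpec) -> tuple[list[str], list[str]]:
    special: list[str] = []
    seen: set[str] = set()
    for genes in spec.marker_sets.values():
        for g in genes:
            if g not in seen:
                special.append(g)
                seen.add(g)
    for c in spec.cluster_profile:
        for g in c.program:
            if g not in seen:
                special.append(g)
                seen.add(g)
    if len(special) > spec.n_genes:
        raise ValidationError(
            f"n_genes={spec.n_genes} smaller than the {len(special)} named genes"
        )
    filler = [f"g{i:05d}" for i in range(spec.n_genes - len(special))]
    return special + filler, special


def _cluster_sizes(spec: SyntheticSpec) -> list[int]:
    bounds = np.round(
        np.cumsum([c.fraction for c in spec.cluster_profile]) * spec.n_cells
    ).astype(int)
    sizes = np.diff(np.concatenate([[0], bounds])).tolist()
    for c, size in zip(spec.cluster_profile, sizes):
        if size == 0:
            raise ValidationError(f"cluster_profile: cluster {c.name!r} has 0 cells")
    return sizes


def generate_vec_dataset(spec: SyntheticSpec) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate a clustered endothelial-like dataset with planted programs.

    Returns a normalized :class:`ExpressionDataset` (counts plus the
    ``ln(TPM/10+1)`` layer) and the ground truth.  Cluster programs shift
    gene means by their log2 fold-changes; clusters listed in
    ``latent_time_clusters`` carry a continuous latent time modulating the
    ``temporal`` marker set through per-gene logistic ramps with random
    midpoints; ``g1s``/``g2m`` marker sets, when present, are boosted in
    cells assigned S / G2M phases.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes, special = _gene_namespace(spec)
    n_genes, n_cells = spec.n_genes, spec.n_cells
    gene_idx = {g: i for i, g in enumerate(genes)}

    # baseline relative abundances; marker/program genes moderately expressed
    weights = rng.lognormal(0.0, 1.0, n_genes)
    for g in special:
        weights[gene_idx[g]] = _MARKER_WEIGHT * rng.lognormal(0.0, 0.25)
    p = weights / weights.sum()

    sizes = _cluster_sizes(spec)
    true_cluster = np.concatenate(
        [np.full(s, c.name, dtype=object) for c, s in zip(spec.cluster_profile, sizes)]
    )
    cells = [f"cell_{i:04d}" for i in range(n_cells)]

    lfc = np.zeros((n_genes, n_cells))
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    for c, start, size in zip(spec.cluster_profile, starts, sizes):
        cols = slice(int(start), int(start) + size)
        for g, value in c.program.items():
            lfc[gene_idx[g], cols] += value

    # continuous latent order along the chain of latent_time_clusters
    latent = np.full(n_cells, np.nan)
    temporal = list(spec.marker_sets.get("temporal", []))
    if spec.latent_time_clusters:
        chain = spec.latent_time_clusters
        k = len(chain)
        for j, name in enumerate(chain):
            mask = true_cluster == name
            latent[mask] = (j + rng.uniform(0, 1, mask.sum())) / k
        if temporal:
            rows = np.array([gene_idx[g] for g in temporal])
            mid = rng.uniform(0.25, 0.75, len(rows))
            sign = np.where(np.arange(len(rows)) % 2 == 0, 1.0, -1.0)
            on = ~np.isnan(latent)
            ramp = 1.0 / (1.0 + np.exp(-(latent[on][None, :] - mid[:, None]) / 0.08))
            lfc[np.ix_(rows, np.flatnonzero(on))] += (
                spec.temporal_log2fc * sign[:, None] * ramp
            )

    # cell-cycle structure
    g1s = [g for g in spec.marker_sets.get("g1s", []) if g in gene_idx]
    g2m = [g for g in spec.marker_sets.get("g2m", []) if g in gene_idx]
    if g1s and g2m:
        phase = rng.choice(["G1", "S", "G2M"], size=n_cells, p=[0.5, 0.25, 0.25])
        lfc[np.ix_([gene_idx[g] for g in g1s], np.flatnonzero(phase == "S"))] += spec.cc_log2fc
        lfc[np.ix_([gene_idx[g] for g in g2m], np.flatnonzero(phase == "G2M"))] += spec.cc_log2fc
    else:
        phase = np.full(n_cells, "G1", dtype=object)

    # negative-binomial counts via the gamma-Poisson mixture
    lib = rng.lognormal(
        np.log(spec.library_size_mean) - 0.5 * _LIB_SIGMA**2, _LIB_SIGMA, n_cells
    )
    mu = p[:, None] * np.exp2(lfc) * lib[None, :]
    r = 1.0 / spec.dispersion
    lam = rng.gamma(shape=r, scale=mu / r)
    counts = rng.poisson(lam).astype(np.int64)

    # observed labels with deliberate flips
    observed = true_cluster.copy()
    flipped: list[str] = []
    if spec.flip_fraction > 0 and len(spec.cluster_profile) > 1:
        n_flip = int(round(spec.flip_fraction * n_cells))
        flip_idx = rng.choice(n_cells, size=n_flip, replace=False)
        names = [c.name for c in spec.cluster_profile]
        for i in flip_idx:
            others = [n for n in names if n != true_cluster[i]]
            observed[i] = others[rng.integers(len(others))]
        flipped = [cells[i] for i in sorted(flip_idx)]

    batch = np.array([f"batch_{b}" for b in rng.integers(spec.batch_count, size=n_cells)])

    # arteriovenous truth from the direction of each cluster's program
    arterial = set(spec.marker_sets.get("arterial", []))
    venous = set(spec.marker_sets.get("venous", []))
    av_of_cluster = {}
    for c in spec.cluster_profile:
        a = sum(c.program.get(g, 0.0) for g in arterial)
        v = sum(c.program.get(g, 0.0) for g in venous)
        av_of_cluster[c.name] = (
            "arterial" if a > 0 >= v else "venous" if v > 0 >= a else "neither"
        )

    cell_meta = pd.DataFrame(
        {"cluster": observed, "batch": batch},
        index=pd.Index(cells, name="cell"),
    )
    dataset = normalize(
        ExpressionDataset(
            counts=counts, genes=genes, cells=cells, cell_meta=cell_meta, platform="well"
        )
    )
    truth_cells = pd.DataFrame(
        {
            "true_cluster": true_cluster,
            "observed_cluster": observed,
            "latent_time": latent,
            "av_identity": [av_of_cluster[c] for c in true_cluster],
            "phase": phase,
            "batch": batch,
        },
        index=pd.Index(cells, name="cell"),
    )
    de_genes = {c.name: {g for g, v in c.program.items() if v != 0} for c in spec.cluster_profile}
    truth = GroundTruth(
        cells=truth_cells,
        de_genes=de_genes,
        temporal_genes=temporal,
        flipped_cells=flipped,
    )
    return dataset, truth


def generate_null_dataset(spec: SyntheticSpec) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate a dataset whose labeled groups share one distribution.

    Requires >= 2 clusters with identical programs; no latent time, flips or
    cell-cycle structure, so every gene is null for every between-group
    contrast.
    """
    spec.validate()
    if len(spec.cluster_profile) < 2:
        raise ValidationError("null spec needs >= 2 clusters")
    programs = [tuple(sorted(c.program.items())) for c in spec.cluster_profile]
    if len(set(programs)) != 1:
        raise ValidationError("null spec requires identical cluster programs")
    if spec.latent_time_clusters or spec.flip_fraction:
        raise ValidationError("null spec must not plant structure")
    dataset, truth = generate_vec_dataset(spec)
    truth.de_genes = {c.name: set() for c in spec.cluster_profile}
    return dataset, truth


# -- two species ---------------------------------------------------------------


def _rename_b(gene: str) -> str:
    return gene.lower() + "_b"


def generate_two_species(
    spec: SyntheticSpec,
) -> tuple[ExpressionDataset, ExpressionDataset, pd.DataFrame, GroundTruth]:
    """Generate two species-linked datasets with planted conserved markers.

    The spec's ``marker_sets`` must name ``conserved`` (up in the AEC1-like
    cluster of both species), ``conserved_arterial`` (up in both arterial
    clusters of both species), ``species_a_only`` and ``species_b_only``
    subsets.  Species A keeps the spec's programs minus the
    ``species_b_only`` genes; species B drops the ``species_a_only`` genes
    and renames its whole namespace, linked back by the returned one-to-one
    homolog map.
    """
    spec.validate()
    required = {"conserved", "species_a_only", "species_b_only"}
    missing = required - set(spec.marker_sets)
    if missing:
        raise ValidationError(f"marker_sets missing {sorted(missing)}")
    a_only = set(spec.marker_sets["species_a_only"])
    b_only = set(spec.marker_sets["species_b_only"])

    def strip(profile: list[ClusterProgram], drop: set[str]) -> list[ClusterProgram]:
        return [
            ClusterProgram(
                c.name, c.fraction, {g: v for g, v in c.program.items() if g not in drop}
            )
            for c in profile
        ]

    base = asdict(spec)
    base.pop("cluster_profile")
    base.pop("marker_sets")
    spec_a = SyntheticSpec(
        **base,
        cluster_profile=strip(spec.cluster_profile, b_only),
        marker_sets=dict(spec.marker_sets),
    )
    base_b = dict(base, seed=spec.seed + 1)
    spec_b = SyntheticSpec(
        **base_b,
        cluster_profile=strip(spec.cluster_profile, a_only),
        marker_sets=dict(spec.marker_sets),
    )

    data_a, truth_a = generate_vec_dataset(spec_a)
    data_b, _ = generate_vec_dataset(spec_b)
    # both species share the generated namespace; species B is renamed
    # wholesale and linked back through a one-to-one homolog map
    data_b = ExpressionDataset(
        counts=data_b.counts,
        genes=[_rename_b(g) for g in data_b.genes],
        cells=["b_" + c for c in data_b.cells],
        norm=data_b.norm,
        cell_meta=data_b.cell_meta.set_index(
            data_b.cell_meta.index.map(lambda c: "b_" + c)
        ),
        platform=data_b.platform,
    )

    homolog_map = pd.DataFrame(
        {
            "species_a": data_a.genes,
            "species_b": [_rename_b(g) for g in data_a.genes],
        }
    )
    truth = GroundTruth(
        cells=truth_a.cells,
        de_genes=truth_a.de_genes,
        conserved_genes={
            "AEC1": set(spec.marker_sets["conserved"]),
            "arterial": set(spec.marker_sets.get("conserved_arterial", [])),
        },
        species_specific={"A": a_only, "B": b_only},
    )
    return data_a, data_b, homolog_map, truth


# -- mural-cell / VEC pair -----------------------------------------------------


def generate_mc_vec_pair(
    spec: SyntheticSpec,
) -> tuple[ExpressionDataset, ExpressionDataset, pd.DataFrame, GroundTruth]:
    """Generate a VEC/mural-cell dataset pair with planted ligand–receptor pairs.

    ``marker_sets`` must name ``ligands`` and ``receptors`` (matched by
    position: planted pairs) and may name ``decoy_ligands`` /
    ``decoy_receptors`` (decoy pairs whose receptor side is essentially
    silent).  Planted ligands are strongly expressed in the mural
    compartment and planted receptors in the VEC compartment, so every
    planted pair satisfies the >50 %-expressing rule in the MC→VEC direction
    while decoys fail it.
    """
    spec.validate()
    for key in ("ligands", "receptors"):
        if key not in spec.marker_sets:
            raise ValidationError(f"marker_sets missing {key!r}")
    ligands = spec.marker_sets["ligands"]
    receptors = spec.marker_sets["receptors"]
    if len(ligands) != len(receptors):
        raise ValidationError("ligands and receptors must pair by position")
    decoy_l = spec.marker_sets.get("decoy_ligands", [])
    decoy_r = spec.marker_sets.get("decoy_receptors", [])

    boost = 3.0  # log2FC of the expressing compartment
    silent = -12.0  # drives a gene to effectively zero expression

    def one_sided(expressed: list[str], silenced: list[str]) -> dict[str, float]:
        program = {g: boost for g in expressed}
        program.update({g: silent for g in silenced})
        return program

    base = asdict(spec)
    base.pop("cluster_profile")
    mc_spec = SyntheticSpec(
        **{**base, "seed": spec.seed},
        cluster_profile=[
            ClusterProgram("MC", 1.0, one_sided(list(ligands) + list(decoy_l), list(receptors) + list(decoy_r)))
        ],
    )
    vec_spec = SyntheticSpec(
        **{**base, "seed": spec.seed + 1},
        cluster_profile=[
            ClusterProgram("VEC", 1.0, one_sided(list(receptors), list(ligands) + list(decoy_l) + list(decoy_r)))
        ],
    )
    mc_data, _ = generate_vec_dataset(mc_spec)
    vec_data, _ = generate_vec_dataset(vec_spec)

    planted = list(zip(ligands, receptors))
    decoys = list(zip(decoy_l, decoy_r))
    pair_table = pd.DataFrame(planted + decoys, columns=["ligand", "receptor"])
    truth = GroundTruth(
        cells=pd.concat(
            [
                pd.DataFrame({"compartment": "VEC"}, index=vec_data.cell_meta.index.map(lambda c: "vec_" + c)),
                pd.DataFrame({"compartment": "MC"}, index=mc_data.cell_meta.index.map(lambda c: "mc_" + c)),
            ]
        ),
        planted_pairs=planted,
        decoy_pairs=decoys,
    )
    return vec_data, mc_data, pair_table, truth


# -- spec factories ------------------------------------------------------------


def default_vec_spec(
    n_genes: int = 2000,
    n_cells: int = 800,
    marker_log2fc: float = 2.0,
    n_cluster_markers: int = 20,
    seed: int = 0,
) -> SyntheticSpec:
    """Eight-cluster embryonic-endothelial structure with arterial programs in
    EP2/EP3/EP5/EP7, venous programs in EP1/EP6, a neutral primordial EP0 and
    an EP4 early cluster, plus 20 cluster-specific markers per cluster and
    planted cell-cycle structure."""
    arterial = load_signature("arterial")
    venous = load_signature("venous")
    g1s = load_signature("g1s")
    g2m = load_signature("g2m")
    arterial_clusters = {"EP2", "EP3", "EP5", "EP7"}
    venous_clusters = {"EP1", "EP6"}
    profile = []
    for i in range(8):
        name = f"EP{i}"
        program = {f"mk_{name}_{j}": marker_log2fc for j in range(n_cluster_markers)}
        if name in arterial_clusters:
            program.update({g: marker_log2fc for g in arterial})
        if name in venous_clusters:
            program.update({g: marker_log2fc for g in venous})
        profile.append(ClusterProgram(name, 1.0 / 8.0, program))
    return SyntheticSpec(
        n_genes=n_genes,
        n_cells=n_cells,
        cluster_profile=profile,
        marker_sets={
            "arterial": arterial,
            "venous": venous,
            "g1s": g1s,
            "g2m": g2m,
        },
        seed=seed,
    )


def continuum_spec(
    n_genes: int = 500,
    n_cells: int = 200,
    n_temporal: int = 50,
    seed: int = 0,
) -> SyntheticSpec:
    """A single latent-time continuum with ``n_temporal`` ramped genes,
    emulating the venous-to-arterial plexus axis."""
    temporal = [f"tg_{i:03d}" for i in range(n_temporal)]
    return SyntheticSpec(
        n_genes=n_genes,
        n_cells=n_cells,
        cluster_profile=[ClusterProgram("chain", 1.0, {})],
        latent_time_clusters=["chain"],
        marker_sets={"temporal": temporal},
        seed=seed,
    )


def null_spec(n_genes: int = 1000, n_cells: int = 200, seed: int = 0) -> SyntheticSpec:
    """Two groups of identical distribution for type-I-error calibration."""
    return SyntheticSpec(
        n_genes=n_genes,
        n_cells=n_cells,
        cluster_profile=[
            ClusterProgram("null_1", 0.5, {}),
            ClusterProgram("null_2", 0.5, {}),
        ],
        seed=seed,
    )


def two_species_spec(
    n_genes: int = 600,
    n_cells: int = 600,
    n_conserved: int = 50,
    n_specific: int = 15,
    n_conserved_arterial: int = 10,
    log2fc: float = 2.0,
    seed: int = 0,
) -> SyntheticSpec:
    """Three matched clusters (AEC1, AEC2, VeEC) with planted conserved,
    conserved-arterial and species-specific AEC1 markers."""
    conserved = [f"cons_{i:03d}" for i in range(n_conserved)]
    cons_art = [f"consart_{i:03d}" for i in range(n_conserved_arterial)]
    a_only = [f"aonly_{i:03d}" for i in range(n_specific)]
    b_only = [f"bonly_{i:03d}" for i in range(n_specific)]
    aec1 = {g: log2fc for g in conserved + cons_art + a_only + b_only}
    aec2 = {g: log2fc for g in cons_art}
    return SyntheticSpec(
        n_genes=n_genes,
        n_cells=n_cells,
        cluster_profile=[
            ClusterProgram("AEC1", 1.0 / 3.0, aec1),
            ClusterProgram("AEC2", 1.0 / 3.0, aec2),
            ClusterProgram("VeEC", 1.0 / 3.0, {}),
        ],
        marker_sets={
            "conserved": conserved,
            "conserved_arterial": cons_art,
            "species_a_only": a_only,
            "species_b_only": b_only,
        },
        seed=seed,
    )


def mc_vec_spec(
    n_genes: int = 400,
    n_cells: int = 200,
    n_planted: int = 10,
    n_decoy: int = 10,
    seed: int = 0,
) -> SyntheticSpec:
    """A mural-cell/VEC pair with matched planted and decoy LR pairs."""
    return SyntheticSpec(
        n_genes=n_genes,
        n_cells=n_cells,
        cluster_profile=[ClusterProgram("placeholder", 1.0, {})],
        marker_sets={
            "ligands": [f"Lig{i}" for i in range(n_planted)],
            "receptors": [f"Rec{i}" for i in range(n_planted)],
            "decoy_ligands": [f"DecoyL{i}" for i in range(n_decoy)],
            "decoy_receptors": [f"DecoyR{i}" for i in range(n_decoy)],
        },
        seed=seed,
    )
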