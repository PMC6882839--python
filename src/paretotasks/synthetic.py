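"""Synthetic cohorts with planted Pareto structure and known ground truth.

Tumors are noisy convex combinations of K planted archetype expression
profiles plus a per-cancer-type tissue offset; mixture weights follow a
symmetric Dirichlet whose concentration spans the specialist (near a
vertex) to generalist (interior) regimes. On top of the expression
polytope the generators plant the downstream signals the pipeline is
meant to recover: driver alterations whose effect vectors lie inside
the front subspace, passenger alterations shifted orthogonally to it,
clinical features enriched near archetypes, drugs whose sensitivity
decays with distance to one archetype, and per-tumor single-cell clouds
whose within-tumor spread aligns with the inter-tumor axes by a planted
fraction rho. Every generator is a pure function of (truth, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from paretotasks.io import GeneSetCollection
from paretotasks.preprocess import ExpressionMatrix, PCSpace, PRIMARY_TUMOR

logger = logging.getLogger(__name__)

#: marker genes switched on in planted non-cancer cells (immune, CAF,
#: endothelial), used by the heterogeneity module's exclusion step
NON_CANCER_MARKERS = ("PTPRC", "PDGFRA", "ZEB1", "ACTA2", "PECAM1")

# fixed per-operation seed offsets so generators draw independent streams
_OP_TUMORS = 1
_OP_ALTERATIONS = 2
_OP_DRUGS = 3
_OP_CELLS = 4
_OP_CLINICAL = 5
_OP_GENESETS = 6


@dataclass
class DriverSpec:
    name: str
    carrier_fraction: float
    target_archetype: int
    effect_magnitude: float
    in_front: bool = True
    label: str = "driver"  # driver | other_cancer_gene | passenger


@dataclass
class DrugSpec:
    name: str
    target_archetype: int | None  # None = untargeted control
    baseline_aoc: float = 1.0
    decay_slope: float = 0.0
    noise_sd: float = 0.05


@dataclass
class ClinicalSpec:
    name: str
    kind: str  # continuous | discrete
    linked_archetype: int | None
    effect_size: float = 1.0


@dataclass
class SyntheticTruth:
    """Planted ground truth: the recovery target for every test."""

    archetypes: np.ndarray  # K x G log2 expression profiles
    weights: np.ndarray  # N x K convex mixture weights
    tissue_offsets: np.ndarray  # T x G per-type mean shifts
    sample_types: np.ndarray  # N integer type assignment
    noise_sd: float
    gene_ids: list[str]
    driver_specs: list[DriverSpec] = field(default_factory=list)
    drug_specs: list[DrugSpec] = field(default_factory=list)
    clinical_specs: list[ClinicalSpec] = field(default_factory=list)
    sc_alignment: float = 0.5  # rho: planted intra/inter alignment fraction
    seed: int = 0
    archetype_blocks: list[list[str]] = field(default_factory=list)
    non_primary_fraction: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < -1e-12).any() or np.abs(w.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("weights rows must be convex (nonnegative, sum 1)")
        if self.archetypes.shape[0] < 3:
            raise ValueError("at least 3 archetypes required")
        if not 0.0 <= self.sc_alignment <= 1.0:
            raise ValueError("sc_alignment rho must be in [0, 1]")
        for spec in self.driver_specs:
            if not 0.0 < spec.carrier_fraction < 1.0:
                raise ValueError(f"carrier fraction for {spec.name} must be in (0,1)")

    @property
    def n_archetypes(self) -> int:
        return self.archetypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.weights.shape[0]

    @property
    def n_genes(self) -> int:
        return self.archetypes.shape[1]

    def front_basis_genes(self) -> np.ndarray:
        """Orthonormal basis (G x K-1) of the planted front's direction space."""
        diffs = (self.archetypes[1:] - self.archetypes[0]).T
        q, _ = np.linalg.qr(diffs)
        return q

    def _rng(self, op: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, op])


def make_truth(
    n_samples: int = 500,
    n_archetypes: int = 3,
    n_genes: int = 200,
    n_types: int = 1,
    block_size: int = 30,
    block_effect: float = 2.0,
    dirichlet_concentration: float = 0.3,
    noise_sd: float = 0.1,
    tissue_offset_sd: float = 1.0,
    sc_alignment: float = 0.5,
    non_primary_fraction: float = 0.0,
    driver_specs: list[DriverSpec] | None = None,
    drug_specs: list[DrugSpec] | None = None,
    clinical_specs: list[ClinicalSpec] | None = None,
    seed: int = 0,
) -> SyntheticTruth:
    """Build a planted truth with block-structured archetypes.

    Each archetype over-expresses a disjoint block of ``block_size``
    genes by ``block_effect`` log2 units (its task signature); the
    remaining genes carry archetype-specific dense structure of smaller
    amplitude so the front is supported by many genes, not only the
    blocks. Gene ids are zero-padded; the non-cancer marker genes are
    appended to the universe for single-cell runs.
    """
    k = n_archetypes
    if block_size * k > n_genes:
        raise ValueError("archetype blocks exceed the gene universe")
    if block_size < 1:
        raise ValueError("block size must be >= 1")
    if n_samples < k:
        raise ValueError("cannot witness all vertices: n_samples < n_archetypes")
    rng = np.random.default_rng([seed, 0])
    gene_ids = [f"G{i:05d}" for i in range(n_genes)] + list(NON_CANCER_MARKERS)
    g_total = len(gene_ids)
    archetypes = np.zeros((k, g_total))
    # diffuse support: every archetype also moves many non-block genes a little
    archetypes[:, :n_genes] = rng.normal(0.0, block_effect / 4.0, size=(k, n_genes))
    blocks: list[list[str]] = []
    for a in range(k):
        lo, hi = a * block_size, (a + 1) * block_size
        archetypes[a, lo:hi] += block_effect
        blocks.append(gene_ids[lo:hi])
    weights = rng.dirichlet([dirichlet_concentration] * k, size=n_samples)
    sample_types = rng.integers(n_types, size=n_samples)
    tissue_offsets = (
        rng.normal(0.0, tissue_offset_sd, size=(n_types, g_total))
        if n_types > 1
        else np.zeros((1, g_total))
    )
    return SyntheticTruth(
        archetypes=archetypes,
        weights=weights,
        tissue_offsets=tissue_offsets,
        sample_types=sample_types,
        noise_sd=noise_sd,
        gene_ids=gene_ids,
        driver_specs=list(driver_specs or []),
        drug_specs=list(drug_specs or []),
        clinical_specs=list(clinical_specs or []),
        sc_alignment=sc_alignment,
        non_primary_fraction=non_primary_fraction,
        archetype_blocks=blocks,
        seed=seed,
    )


def generate_tumors(truth: SyntheticTruth) -> ExpressionMatrix:
    """Expression = weights . archetypes + tissue offset + Gaussian noise.

    Metadata carries ``cancer_type`` and ``sample_type``; a configurable
    fraction of samples is flagged as metastatic to exercise the
    primary-tumor filter.
    """
    rng = truth._rng(_OP_TUMORS)
    w, arch = truth.weights, truth.archetypes
    values = w @ arch + truth.tissue_offsets[truth.sample_types]
    if truth.noise_sd > 0:
        values = values + rng.normal(0.0, truth.noise_sd, size=values.shape)
    sample_ids = [f"S{i:05d}" for i in range(truth.n_samples)]
    sample_type = np.full(truth.n_samples, PRIMARY_TUMOR, dtype=object)
    if truth.non_primary_fraction > 0:
        flip = rng.random(truth.n_samples) < truth.non_primary_fraction
        sample_type[flip] = "Metastatic"
    metadata = pd.DataFrame(
        {
            "cancer_type": [f"TYPE{t}" for t in truth.sample_types],
            "sample_type": sample_type,
        },
        index=sample_ids,
    )
    return ExpressionMatrix(
        pd.DataFrame(values, index=sample_ids, columns=truth.gene_ids), metadata
    )


def generate_alterations(
    truth: SyntheticTruth, expr: ExpressionMatrix
) -> tuple[pd.DataFrame, pd.DataFrame, ExpressionMatrix]:
    """Binary alteration matrix, label table, and the altered expression.

    In-front drivers: carrier probability increases with the tumor's
    weight on the target archetype, and carriers receive a shift of the
    stated magnitude along (target archetype - weight centroid), a
    direction inside the front span. Passengers: carriers uniform at
    random, shift along a random direction orthogonalized against the
    front span. Returns (alterations, labels, modified expression).
    """
    rng = truth._rng(_OP_ALTERATIONS)
    n = truth.n_samples
    values = expr.values.to_numpy(dtype=float).copy()
    front = truth.front_basis_genes()  # G x (K-1)
    centroid = truth.weights.mean(axis=0) @ truth.archetypes
    carriers = {}
    rows = []
    for spec in truth.driver_specs:
        if spec.in_front and spec.effect_magnitude < 0:
            raise ValueError(f"driver {spec.name}: effect magnitude must be >= 0")
        if spec.in_front:
            w_target = truth.weights[:, spec.target_archetype]
            p = spec.carrier_fraction * w_target / max(w_target.mean(), 1e-12)
            mask = rng.random(n) < np.clip(p, 0.0, 1.0)
            direction = truth.archetypes[spec.target_archetype] - centroid
            norm = np.linalg.norm(direction)
            if norm > 0:
                direction = direction / norm
        else:
            mask = rng.random(n) < spec.carrier_fraction
            raw = rng.standard_normal(truth.n_genes)
            raw -= front @ (front.T @ raw)
            direction = raw / np.linalg.norm(raw)
        values[mask] += spec.effect_magnitude * direction
        carriers[spec.name] = mask.astype(int)
        rows.append({"alteration": spec.name, "label": spec.label,
                     "target_archetype": spec.target_archetype if spec.in_front else -1,
                     "in_front": spec.in_front})
    alterations = pd.DataFrame(carriers, index=expr.sample_ids)
    labels = pd.DataFrame(rows).set_index("alteration") if rows else pd.DataFrame(
        columns=["label", "target_archetype", "in_front"]
    )
    modified = ExpressionMatrix(
        pd.DataFrame(values, index=expr.sample_ids, columns=expr.gene_ids),
        expr.metadata,
    )
    return alterations, labels, modified


def generate_drug_panel(
    truth: SyntheticTruth,
    line_scores: np.ndarray,
    archetype_coords: np.ndarray,
    missingness: float = 0.0,
    line_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Cell line x drug GR AOC table with planted archetype-targeted drugs.

    AOC = baseline - slope * distance(line, target archetype) + noise,
    truncated below at 0; untargeted control drugs are archetype
    independent. A missingness mask exercises the minimum-lines-per-bin
    rule downstream.
    """
    rng = truth._rng(_OP_DRUGS)
    scores = np.asarray(line_scores, dtype=float)
    n = scores.shape[0]
    ids = line_ids or [f"LINE{i:03d}" for i in range(n)]
    cols = {}
    for spec in truth.drug_specs:
        if spec.target_archetype is None:
            aoc = np.full(n, spec.baseline_aoc)
        else:
            dist = np.linalg.norm(scores - archetype_coords[spec.target_archetype], axis=1)
            aoc = spec.baseline_aoc - spec.decay_slope * dist
        if spec.noise_sd > 0:
            aoc = aoc + rng.normal(0.0, spec.noise_sd, size=n)
        aoc = np.maximum(aoc, 0.0)
        if missingness > 0:
            aoc = np.where(rng.random(n) < missingness, np.nan, aoc)
        cols[spec.name] = aoc
    return pd.DataFrame(cols, index=ids)


def generate_clinical(truth: SyntheticTruth) -> pd.DataFrame:
    """Clinical feature table with features enriched near planted archetypes.

    Continuous features increase with the weight on the linked archetype
    (effect size in units of the feature's noise SD); discrete features
    are more prevalent there. Unlinked features are pure noise.
    """
    rng = truth._rng(_OP_CLINICAL)
    n = truth.n_samples
    sample_ids = [f"S{i:05d}" for i in range(n)]
    cols = {}
    for spec in truth.clinical_specs:
        if spec.linked_archetype is not None:
            w = truth.weights[:, spec.linked_archetype]
        else:
            w = np.zeros(n)
        if spec.kind == "continuous":
            cols[spec.name] = spec.effect_size * w + rng.standard_normal(n)
        elif spec.kind == "discrete":
            base = 0.15
            p = np.clip(base + spec.effect_size * w, 0.0, 1.0)
            cols[spec.name] = (rng.random(n) < p).astype(int)
        else:
            raise ValueError(f"unknown clinical feature kind {spec.kind!r}")
    return pd.DataFrame(cols, index=sample_ids)


def generate_single_cells(
    truth: SyntheticTruth,
    tumor_expr: ExpressionMatrix,
    pc_space: PCSpace,
    n_tumors: int = 6,
    cells_per_tumor: int = 120,
    n_axes: int = 5,
    cell_spread_sd: float = 0.5,
    depth: float = 2000.0,
    non_cancer_fraction: float = 0.0,
    marker_level: float = 6.0,
    marker_off_level: float = -10.0,
    poisson: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell counts and covariates with planted intra/inter alignment rho.

    Cell log2 profile = tumor centroid + sqrt(rho) * displacement inside
    the span of the top ``n_axes`` inter-tumor PCs + sqrt(1-rho) *
    isotropic displacement. Counts are Poisson draws on scaled
    exponentiated log-means so detectable-gene counts vary per cell;
    ``poisson=False`` emits the underlying log2 profiles directly (the
    infinite-depth limit, useful for recovering the planted alignment
    without sampling noise). A fraction of cells is emitted as
    non-cancer with the marker genes switched on. Covariates: total
    count, mitochondrial fraction, tumor id, planted non-cancer flag.
    """
    if cells_per_tumor < 20:
        raise ValueError("at least 20 cells per tumor required")
    rng = truth._rng(_OP_CELLS)
    rho = truth.sc_alignment
    genes = list(tumor_expr.gene_ids)
    g = len(genes)
    n_axes = min(n_axes, pc_space.n_components)
    loadings = pc_space.loadings.to_numpy()[:, :n_axes]  # G x m
    tumor_ids = list(tumor_expr.sample_ids[:n_tumors])
    profiles = tumor_expr.values.loc[tumor_ids].to_numpy()
    marker_idx = [genes.index(m) for m in NON_CANCER_MARKERS if m in genes]
    records, counts = [], []
    cell_ids = []
    for ti, tumor in enumerate(tumor_ids):
        for ci in range(cells_per_tumor):
            aligned = loadings @ rng.normal(0.0, cell_spread_sd, size=n_axes)
            iso = rng.normal(0.0, cell_spread_sd / np.sqrt(g / n_axes), size=g)
            logp = profiles[ti] + np.sqrt(rho) * aligned + np.sqrt(1.0 - rho) * iso
            non_cancer = rng.random() < non_cancer_fraction
            if non_cancer_fraction > 0:
                # markers silent in cancer cells, switched on otherwise;
                # untouched when no exclusion is being exercised
                logp[marker_idx] = marker_level if non_cancer else marker_off_level
            if poisson:
                rate = 2.0**logp
                rate = rate / rate.sum() * depth
                counts.append(rng.poisson(rate))
            else:
                counts.append(logp)
            total = float(np.abs(counts[-1]).sum())
            records.append(
                {
                    "tumor_id": tumor,
                    "total_count": total,
                    "mito_fraction": float(rng.uniform(0.01, 0.15)),
                    "planted_non_cancer": int(non_cancer),
                }
            )
            cell_ids.append(f"{tumor}_C{ci:04d}")
    counts_df = pd.DataFrame(np.asarray(counts), index=cell_ids, columns=genes)
    covariates = pd.DataFrame(records, index=cell_ids)
    return counts_df, covariates


def generate_gene_sets(
    truth: SyntheticTruth,
    n_decoys: int = 10,
    decoy_size: int = 20,
) -> GeneSetCollection:
    """One task set per archetype (its over-expressed block) plus random decoys."""
    rng = truth._rng(_OP_GENESETS)
    if not truth.archetype_blocks:
        # blocks are the leading disjoint gene ranges used by make_truth
        raise ValueError("truth has no archetype blocks; use make_truth")
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for a, block in enumerate(truth.archetype_blocks):
        sets[f"TASK_SET_{a}"] = list(block)
        descriptions[f"TASK_SET_{a}"] = f"planted task signature of archetype {a}"
    for i in range(n_decoys):
        members = list(rng.choice(truth.gene_ids, size=decoy_size, replace=False))
        sets[f"DECOY_SET_{i}"] = members
        descriptions[f"DECOY_SET_{i}"] = "random decoy set"
    return GeneSetCollection(sets, descriptions)
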