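"""Synthetic inputs with known ground truth for every pipeline stage.

Everything the pipeline consumes can be generated here: genomes whose
genes share a modal codon usage with a controllable alien (HGT)
fraction, protein sequences with planted LplA-N motifs, per-species
gene inventories with configurable system frequencies and aerobe
concordance, and random additive trees with their distance matrices.
All randomness flows through :func:`numpy.random.default_rng` seeded
from a single integer, so identical seeds give identical outputs.

Codon model: a genome's resident usage profile is drawn per synonymous
family from a symmetric Dirichlet with the configured concentration
(large concentration → near-uniform within each family).  An alien
profile is an independent draw mixed with the resident profile at
weight exp(−divergence): divergence 0 reproduces the resident profile
exactly and the effect grows monotonically.  Amino-acid composition is
shared by resident and alien genes — only the synonymous choice
differs, which is exactly what a modal-usage screen keys on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .codon_hgt import ModalUsageProfile
from .errors import ParameterError
from .genetic_code import INFORMATIVE_FAMILIES
from .motifs import AA_ALPHABET, MotifPattern
from .nj import DistanceMatrix, TreeNode, tree_to_distances
from .pathway import SpeciesInventory

MIN_GENE_LENGTH_CODONS = 30


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic genome."""

    seed: int
    n_genes: int = 500
    gene_length_codons: tuple[int, int] = (100, 500)  # log-uniform range
    hgt_fraction: float = 0.0
    profile_concentration: float = 1.0
    alien_divergence: float = 3.0
    genetic_code_id: int = 11

    def __post_init__(self) -> None:
        if not 0.0 <= self.hgt_fraction <= 1.0:
            raise ParameterError("hgt_fraction must lie in [0, 1]")
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        lo, hi = self.gene_length_codons
        if lo < MIN_GENE_LENGTH_CODONS or hi < lo:
            raise ParameterError(
                f"gene lengths must satisfy {MIN_GENE_LENGTH_CODONS} <= lo <= hi"
            )
        if self.profile_concentration <= 0:
            raise ParameterError("profile_concentration must be positive")
        if self.alien_divergence < 0:
            raise ParameterError("alien_divergence must be nonnegative")


@dataclass
class GroundTruth:
    """Ground-truth sidecar for any simulated entity set."""

    hgt_labels: dict[str, bool] = field(default_factory=dict)
    motif_positions: dict[str, list[int]] = field(default_factory=dict)
    tree: Optional[TreeNode] = None
    inventory_params: dict = field(default_factory=dict)
    resident_profile: Optional[dict[str, float]] = None
    alien_profile: Optional[dict[str, float]] = None
    phenotypes: dict[str, str] = field(default_factory=dict)
    complete_pathway: dict[str, bool] = field(default_factory=dict)


def gen_profile(
    seed: int | np.random.Generator,
    concentration: float = 1.0,
    genetic_code_id: int = 11,
) -> dict[str, float]:
    """Random usage profile: per-family symmetric Dirichlet(concentration).

    Single-codon families (Met, Trp) and stops are excluded; within every
    family the frequencies are positive and sum to 1.
    """
    if concentration <= 0:
        raise ParameterError("concentration must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    freqs: dict[str, float] = {}
    for aa in sorted(INFORMATIVE_FAMILIES):
        codons = INFORMATIVE_FAMILIES[aa]
        draw = rng.dirichlet([concentration] * len(codons))
        # keep strictly positive for log-based statistics downstream
        draw = np.clip(draw, 1e-9, None)
        draw = draw / draw.sum()
        for codon, f in zip(codons, draw):
            freqs[codon] = float(f)
    return freqs


def _mix_profiles(
    resident: dict[str, float], other: dict[str, float], divergence: float
) -> dict[str, float]:
    w = math.exp(-divergence)
    mixed = {c: w * resident[c] + (1 - w) * other[c] for c in resident}
    # renormalize per family (exact up to float error already)
    for codons in INFORMATIVE_FAMILIES.values():
        s = sum(mixed[c] for c in codons)
        for c in codons:
            mixed[c] /= s
    return mixed


def _sample_gene(
    rng: np.random.Generator, n_codons: int, freqs: dict[str, float]
) -> str:
    """In-frame CDS: ATG + codons sampled from the profile + stop."""
    fams = sorted(INFORMATIVE_FAMILIES)
    aa_choices = rng.choice(len(fams), size=n_codons)
    codons = []
    for k in aa_choices:
        family = INFORMATIVE_FAMILIES[fams[k]]
        probs = np.array([freqs[c] for c in family])
        codons.append(family[rng.choice(len(family), p=probs / probs.sum())])
    return "ATG" + "".join(codons) + "TAA"


def gen_genome(config: SimulationConfig) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Genes from the resident profile, a labelled fraction from an alien one."""
    rng = np.random.default_rng(config.seed)
    resident = gen_profile(rng, config.profile_concentration)
    independent = gen_profile(rng, config.profile_concentration)
    alien = _mix_profiles(resident, independent, config.alien_divergence)
    lo, hi = config.gene_length_codons
    truth = GroundTruth(resident_profile=resident, alien_profile=alien)
    records: list[tuple[str, str]] = []
    for i in range(config.n_genes):
        gene_id = f"gene_{i:05d}"
        is_alien = bool(rng.random() < config.hgt_fraction)
        n_codons = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        n_codons = max(MIN_GENE_LENGTH_CODONS, min(n_codons, hi))
        seq = _sample_gene(rng, n_codons, alien if is_alien else resident)
        records.append((gene_id, seq))
        truth.hgt_labels[gene_id] = is_alien
    return records, truth


def gen_motif_sequences(
    n: int,
    length: int,
    motif: MotifPattern,
    planted_per_seq: int = 1,
    background_freqs: Optional[dict[str, float]] = None,
    seed: int = 0,
    plant_positions: Optional[Sequence[int]] = None,
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Random protein sequences with exact motif copies planted.

    Planted occurrences match the consensus exactly (one residue drawn
    from each position's allowed set) at recorded 1-based starts; when
    ``plant_positions`` is given those starts are used for every
    sequence instead of random non-overlapping ones.
    """
    m = len(motif)
    if m > length:
        raise ParameterError("motif longer than sequence")
    if planted_per_seq * m > length:
        raise ParameterError("too many planted copies for the sequence length")
    rng = np.random.default_rng(seed)
    alphabet = sorted(background_freqs) if background_freqs else sorted(AA_ALPHABET)
    if background_freqs:
        probs = np.array([background_freqs[a] for a in alphabet], dtype=float)
        probs = probs / probs.sum()
    else:
        probs = np.full(len(alphabet), 1.0 / len(alphabet))
    truth = GroundTruth()
    records: list[tuple[str, str]] = []
    for i in range(n):
        seq_id = f"prot_{i:05d}"
        seq = list(rng.choice(alphabet, size=length, p=probs))
        if plant_positions is not None:
            starts = sorted(int(s) for s in plant_positions)
            if any(s < 1 or s + m - 1 > length for s in starts):
                raise ParameterError("plant position outside sequence")
        else:
            starts = _nonoverlapping_starts(rng, planted_per_seq, length, m)
        for s in starts:
            for offset, pos_set in enumerate(motif.positions):
                choices = sorted(pos_set)
                seq[s - 1 + offset] = choices[rng.choice(len(choices))]
        records.append((seq_id, "".join(seq)))
        truth.motif_positions[seq_id] = list(starts)
    return records, truth


def _nonoverlapping_starts(
    rng: np.random.Generator, k: int, length: int, m: int
) -> list[int]:
    starts: list[int] = []
    attempts = 0
    while len(starts) < k and attempts < 1000:
        s = int(rng.integers(1, length - m + 2))
        if all(abs(s - t) >= m for t in starts):
            starts.append(s)
        attempts += 1
    if len(starts) < k:
        raise ParameterError("could not place non-overlapping motif copies")
    return sorted(starts)


DEFAULT_SYSTEM_FREQS = {"LplA": 0.34, "LipM": 0.30, "LipB": 0.06}

_SYSTEM_GENES = {
    "LplA": {"lpla_n": 1, "lpla_c": 1},
    "LipM": {"lipm": 1, "lipa": 1},
    "LipB": {"lipb": 1, "lipa": 1},
}


def gen_inventory(
    n_species: int,
    system_freqs: Optional[dict[str, float]] = None,
    co_retention_spec: Optional[dict[str, float]] = None,
    oxygen_concordance: float = 0.9,
    seed: int = 0,
    p_aerobe: float = 0.5,
    anaerobe_complete_prob: float = 0.02,
) -> tuple[list[SpeciesInventory], GroundTruth]:
    """Species inventories with a configured genotype–phenotype concordance.

    Each species is an aerobe with probability ``p_aerobe``.  Aerobes
    receive a complete pathway (a transferase system drawn by
    ``system_freqs`` plus LipA/E2 as that system requires) with
    probability ``oxygen_concordance``; anaerobes with probability
    ``anaerobe_complete_prob``.  Species without a complete pathway are
    empty or — per ``co_retention_spec`` ``{"partial": p}`` — carry a
    transferase without its substrate.
    """
    if not 0.0 <= oxygen_concordance <= 1.0:
        raise ParameterError("oxygen_concordance must lie in [0, 1]")
    if not 0.0 <= p_aerobe <= 1.0:
        raise ParameterError("p_aerobe must lie in [0, 1]")
    freqs = dict(DEFAULT_SYSTEM_FREQS if system_freqs is None else system_freqs)
    for name, f in freqs.items():
        if name not in _SYSTEM_GENES:
            raise ParameterError(f"unknown system {name!r}")
        if not 0.0 <= f <= 1.0:
            raise ParameterError(f"system frequency for {name} outside [0, 1]")
    p_partial = 0.3
    if co_retention_spec:
        for key, val in co_retention_spec.items():
            if key != "partial":
                if key not in freqs or freqs[key] == 0.0:
                    raise ParameterError(
                        f"co-retention conditioned on absent system {key!r}"
                    )
            if not 0.0 <= val <= 1.0:
                raise ParameterError("co-retention probabilities must lie in [0, 1]")
        p_partial = co_retention_spec.get("partial", p_partial)
    total = sum(freqs.values())
    systems = sorted(freqs)
    sys_probs = (
        np.array([freqs[s] for s in systems]) / total if total > 0 else None
    )
    rng = np.random.default_rng(seed)
    truth = GroundTruth(
        inventory_params={
            "n_species": n_species,
            "system_freqs": freqs,
            "oxygen_concordance": oxygen_concordance,
            "p_aerobe": p_aerobe,
            "anaerobe_complete_prob": anaerobe_complete_prob,
        }
    )
    inventories: list[SpeciesInventory] = []
    for i in range(n_species):
        sid = f"sp_{i:05d}"
        aerobe = bool(rng.random() < p_aerobe)
        p_complete = oxygen_concordance if aerobe else anaerobe_complete_prob
        complete = bool(rng.random() < p_complete) and sys_probs is not None
        counts = {c: 0 for c in ("lpla_n", "lpla_c", "lpla_fused", "lipa",
                                 "lipb", "lipm", "lipl", "e2", "gcvh",
                                 "lipoyl_only")}
        if complete:
            system = systems[int(rng.choice(len(systems), p=sys_probs))]
            counts.update(_SYSTEM_GENES[system])
            counts["e2"] = 1
        elif sys_probs is not None and rng.random() < p_partial:
            system = systems[int(rng.choice(len(systems), p=sys_probs))]
            counts.update(_SYSTEM_GENES[system])  # transferase, no substrate
        inventories.append(
            SpeciesInventory(
                species_id=sid,
                order="simulated",
                oxygen_phenotype="aerobe" if aerobe else "obligate_anaerobe",
                **counts,
            )
        )
        truth.phenotypes[sid] = "aerobe" if aerobe else "obligate_anaerobe"
        truth.complete_pathway[sid] = complete
    return inventories, truth


def gen_tree_distances(
    n_taxa: int,
    branch_length_range: tuple[float, float] = (0.05, 1.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[TreeNode, DistanceMatrix]:
    """Random unrooted binary tree and its (optionally noised) distances.

    Topology grows by attaching each new leaf to a uniformly chosen
    branch; branch lengths are uniform in ``branch_length_range``.  The
    returned matrix is the tree's path-length matrix plus symmetric
    i.i.d. Gaussian noise (zero diagonal preserved).
    """
    if n_taxa < 3:
        raise ParameterError("need at least 3 taxa")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be nonnegative")
    lo, hi = branch_length_range
    if not 0 < lo <= hi:
        raise ParameterError("branch lengths must be positive with lo <= hi")
    rng = np.random.default_rng(seed)

    def blen() -> float:
        return float(rng.uniform(lo, hi))

    names = [f"t{i}" for i in range(n_taxa)]
    root = TreeNode(
        children=[TreeNode(name=names[k], length=blen()) for k in range(3)]
    )
    edges: list[tuple[TreeNode, TreeNode]] = [(root, c) for c in root.children]
    for k in range(3, n_taxa):
        parent, child = edges[int(rng.integers(len(edges)))]
        split = float(rng.uniform(0.1, 0.9))
        mid = TreeNode(length=child.length * (1 - split))
        child.length = child.length * split
        leaf = TreeNode(name=names[k], length=blen())
        parent.children[parent.children.index(child)] = mid
        mid.children = [child, leaf]
        edges.append((parent, mid))
        edges.append((mid, child))
        edges.append((mid, leaf))
        edges.remove((parent, child))
    dist = tree_to_distances(root, taxa=names)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=dist.values.shape)
        noise = np.triu(noise, k=1)
        values = dist.values + noise + noise.T
        dist = DistanceMatrix(taxa=dist.taxa, values=values)
    return root, dist
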