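"""Rule engine: gene inventories -> lipoylation systems, completeness, aerobiosis.

Biology encoded here:

* Three transferase systems attach (octanoyl-)lipoyl groups to the E2
  lipoyl domain: the ligase LplA — in archaea usually a bipartite
  LplA-N + LplA-C pair, occasionally a single fused gene — and the
  octanoyl transferases LipM and LipB, which both require the lipoate
  synthetase LipA downstream.
* Substrates: OADHC E2 (lipoyl domain + PF00198 acyltransferase domain),
  the glycine-cleavage H protein (GcvH), and orphan single lipoyl-domain
  proteins.
* A complete E2 route (transferase + any required LipA + E2) is the
  genomic signature of aerobic metabolic capability; total absence of
  lipoylation genes is the streamlined-anaerobe signature.

LipL (the Firmicute lipoyl amidotransferase) is carried in the schema
for completeness but never satisfies any route: no archaeal LipL exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import DataError

OXYGEN_PHENOTYPES = (
    "aerobe",
    "facultative",
    "aerotolerant_anaerobe",
    "obligate_anaerobe",
    "unknown",
)

#: phenotypes counted as oxygen-exposed when scoring concordance
AEROBIC_PHENOTYPES = frozenset({"aerobe", "facultative", "aerotolerant_anaerobe"})

GENE_FAMILY_COLUMNS = (
    "lpla_n",
    "lpla_c",
    "lpla_fused",
    "lipa",
    "lipb",
    "lipm",
    "lipl",
    "e2",
    "gcvh",
    "lipoyl_only",
)


@dataclass(frozen=True)
class SpeciesInventory:
    """Per-species gene-family copy numbers plus the oxygen phenotype label."""

    species_id: str
    order: str = ""
    lpla_n: int = 0
    lpla_c: int = 0
    lpla_fused: int = 0
    lipa: int = 0
    lipb: int = 0
    lipm: int = 0
    lipl: int = 0
    e2: int = 0
    gcvh: int = 0
    lipoyl_only: int = 0
    oxygen_phenotype: str = "unknown"
    hgt_flagged: int = 0

    def __post_init__(self) -> None:
        for col in GENE_FAMILY_COLUMNS + ("hgt_flagged",):
            if getattr(self, col) < 0:
                raise DataError(f"{self.species_id}: negative count for {col}")
        if self.oxygen_phenotype not in OXYGEN_PHENOTYPES:
            raise DataError(
                f"{self.species_id}: unknown phenotype {self.oxygen_phenotype!r}"
            )

    @property
    def transferase_gene_count(self) -> int:
        """Genes in the cofactor-transferase family (LplA-N incl. fused, LipM, LipB)."""
        return self.lpla_n + self.lpla_fused + self.lipm + self.lipb

    @property
    def total_lipoylation_genes(self) -> int:
        return sum(getattr(self, col) for col in GENE_FAMILY_COLUMNS)


@dataclass
class SystemCall:
    """Derived per-species calls; produced by the rule engine."""

    species_id: str
    systems: frozenset[str] = frozenset()
    complete_routes: frozenset[str] = frozenset()
    substrates: frozenset[str] = frozenset()
    exclusive_single_system: bool = False
    lpla_complete_via_gcvh_only: bool = False
    aerobiosis_prediction: str = "indeterminate"
    audit: list[str] = field(default_factory=list)
    inventory: Optional[SpeciesInventory] = None


def classify_substrate(domain_architecture: Sequence[str]) -> str:
    """Class of a lipoyl-domain protein from its ordered domain labels.

    Labels are matched case-insensitively; the acyltransferase catalytic
    domain is recognized as ``PF00198`` or ``acyltransferase``.
    """
    if not domain_architecture:
        raise DataError("empty domain architecture")
    labels = {d.strip().lower() for d in domain_architecture}
    has_lipoyl = "lipoyl" in labels
    if not has_lipoyl:
        return "none"
    if "pf00198" in labels or "acyltransferase" in labels:
        return "E2"
    if "gcvh" in labels:
        return "GcvH"
    return "LipoylOnly"


def resolve_ambiguous_transferase(inventory: SpeciesInventory) -> str:
    """Resolve a Clade-II-like LplA-N/LipM-ambiguous candidate.

    Correlated presence of the partner adenylation gene LplA-C argues for
    LplA-N; presence of LipA (required downstream of LipM, never of LplA)
    argues for LipM.  Conflicting or absent evidence is left unresolved.
    """
    has_lpla_c = inventory.lpla_c >= 1
    has_lipa = inventory.lipa >= 1
    if has_lpla_c and not has_lipa:
        return "LplA_N"
    if has_lipa and not has_lpla_c:
        return "LipM"
    return "unresolved"


def classify_systems(inventory: SpeciesInventory) -> SystemCall:
    """Which transferase systems the genome encodes.

    LplA requires both halves of the bipartite gene pair (or a fused
    copy); LipM and LipB each require a single gene.
    """
    systems = set()
    audit: list[str] = []
    if (inventory.lpla_n >= 1 and inventory.lpla_c >= 1) or inventory.lpla_fused >= 1:
        systems.add("LplA")
    elif inventory.lpla_n >= 1:
        audit.append("LplA-N present without LplA-C or fused gene: no LplA system")
    elif inventory.lpla_c >= 1:
        audit.append("orphan LplA-C present")
    if inventory.lipm >= 1:
        systems.add("LipM")
    if inventory.lipb >= 1:
        systems.add("LipB")
    if inventory.lipl >= 1:
        audit.append("LipL recorded but never satisfies an archaeal route")
    if systems == {"LplA"} and inventory.lipa >= 1:
        audit.append("anomaly: LipA present with LplA as sole transferase system")
    return SystemCall(
        species_id=inventory.species_id,
        systems=frozenset(systems),
        exclusive_single_system=len(systems) == 1,
        audit=audit,
        inventory=inventory,
    )


def assess_completeness(call: SystemCall, inventory: SpeciesInventory) -> SystemCall:
    """Fill in complete routes and substrate repertoire.

    LipB and LipM routes need LipA and E2; the LplA route needs E2, or —
    flagged separately — GcvH as the alternative lipoylation target.
    """
    routes = set()
    has_e2 = inventory.e2 >= 1
    has_gcvh = inventory.gcvh >= 1
    gcvh_only = False
    if "LipB" in call.systems and inventory.lipa >= 1 and has_e2:
        routes.add("LipB_route")
    if "LipM" in call.systems and inventory.lipa >= 1 and has_e2:
        routes.add("LipM_route")
    if "LplA" in call.systems and (has_e2 or has_gcvh):
        routes.add("LplA_route")
        gcvh_only = not has_e2
        if gcvh_only:
            call.audit.append("LplA route complete via GcvH only")
    substrates = set()
    if has_e2:
        substrates.add("E2")
    if has_gcvh:
        substrates.add("GcvH")
    if inventory.lipoyl_only >= 1:
        substrates.add("LipoylOnly")
    call.complete_routes = frozenset(routes)
    call.substrates = frozenset(substrates)
    call.lpla_complete_via_gcvh_only = gcvh_only
    return call


def predict_aerobiosis(call: SystemCall) -> SystemCall:
    """Aerobiosis verdict from the completed call.

    Any route complete with the OADHC E2 substrate marks the species
    aerobic-capable; a genome with no lipoylation genes at all is
    consistent with obligate anaerobiosis; anything in between —
    transferase without substrate, or a GcvH-only LplA route — is
    indeterminate.
    """
    inv = call.inventory
    if inv is None:
        raise DataError("call lacks its inventory; run classify_systems first")
    e2_routes = call.complete_routes - (
        {"LplA_route"} if call.lpla_complete_via_gcvh_only else set()
    )
    if e2_routes:
        call.aerobiosis_prediction = "aerobic_capable"
    elif inv.total_lipoylation_genes == 0:
        call.aerobiosis_prediction = "anaerobe_consistent"
    else:
        call.aerobiosis_prediction = "indeterminate"
    return call


def call_species(inventory: SpeciesInventory) -> SystemCall:
    """Full rule chain for one species (pure function of the inventory)."""
    call = classify_systems(inventory)
    call = assess_completeness(call, inventory)
    return predict_aerobiosis(call)


def call_inventories(inventories: Iterable[SpeciesInventory]) -> list[SystemCall]:
    return [call_species(inv) for inv in inventories]


@dataclass
class RetentionSummary:
    """Marginal counts of the per-species calls, mirroring the study's tallies."""

    n_species: int
    n_with_system: int
    n_without_pathway: int
    n_exclusive_single_system: int
    pct_exclusive_single_system: float
    species_per_system: dict[str, int]
    genes_per_system: dict[str, int]
    total_transferase_genes: int
    lipm_with_lipa: int
    lipm_with_lipa_and_e2: int
    lipb_with_lipa_and_e2: int
    lpla_with_e2: int
    n_hgt_flagged: int
    pct_hgt_flagged: float

    def as_dict(self) -> dict:
        return {
            "n_species": self.n_species,
            "n_with_system": self.n_with_system,
            "n_without_pathway": self.n_without_pathway,
            "n_exclusive_single_system": self.n_exclusive_single_system,
            "pct_exclusive_single_system": self.pct_exclusive_single_system,
            "species_per_system": dict(self.species_per_system),
            "genes_per_system": dict(self.genes_per_system),
            "total_transferase_genes": self.total_transferase_genes,
            "lipm_with_lipa": self.lipm_with_lipa,
            "lipm_with_lipa_and_e2": self.lipm_with_lipa_and_e2,
            "lipb_with_lipa_and_e2": self.lipb_with_lipa_and_e2,
            "lpla_with_e2": self.lpla_with_e2,
            "n_hgt_flagged": self.n_hgt_flagged,
            "pct_hgt_flagged": self.pct_hgt_flagged,
        }


def summarize_retention(calls: Sequence[SystemCall]) -> RetentionSummary:
    """Co-retention and exclusivity tallies over a set of species calls."""
    if not calls:
        raise DataError("no calls to summarize")
    invs = []
    for c in calls:
        if c.inventory is None:
            raise DataError(f"{c.species_id}: call lacks inventory")
        invs.append(c.inventory)

    with_system = [c for c in calls if c.systems]
    exclusive = [c for c in with_system if c.exclusive_single_system]
    species_per_system = {
        sys_name: sum(1 for c in calls if sys_name in c.systems)
        for sys_name in ("LplA", "LipM", "LipB")
    }
    genes_per_system = {
        "LplA": sum(i.lpla_n + i.lpla_fused for i in invs),
        "LipM": sum(i.lipm for i in invs),
        "LipB": sum(i.lipb for i in invs),
    }
    total_genes = sum(i.transferase_gene_count for i in invs)
    lipm_calls = [c for c in calls if "LipM" in c.systems]
    lipb_calls = [c for c in calls if "LipB" in c.systems]
    lpla_calls = [c for c in calls if "LplA" in c.systems]
    n_flagged = sum(i.hgt_flagged for i in invs)
    return RetentionSummary(
        n_species=len(calls),
        n_with_system=len(with_system),
        n_without_pathway=len(calls) - len(with_system),
        n_exclusive_single_system=len(exclusive),
        pct_exclusive_single_system=(
            100.0 * len(exclusive) / len(with_system) if with_system else 0.0
        ),
        species_per_system=species_per_system,
        genes_per_system=genes_per_system,
        total_transferase_genes=total_genes,
        lipm_with_lipa=sum(1 for c in lipm_calls if c.inventory.lipa >= 1),
        lipm_with_lipa_and_e2=sum(
            1 for c in lipm_calls if c.inventory.lipa >= 1 and c.inventory.e2 >= 1
        ),
        lipb_with_lipa_and_e2=sum(
            1 for c in lipb_calls if c.inventory.lipa >= 1 and c.inventory.e2 >= 1
        ),
        lpla_with_e2=sum(1 for c in lpla_calls if c.inventory.e2 >= 1),
        n_hgt_flagged=n_flagged,
        pct_hgt_flagged=100.0 * n_flagged / total_genes if total_genes else 0.0,
    )
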