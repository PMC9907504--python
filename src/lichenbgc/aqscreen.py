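"""Screen BGC families for the conserved four-gene anthraquinone architecture.

Teloschistales anthraquinone clusters share a core of four genes — an
ABC-transporter efflux pump, a standalone metallo-beta-lactamase-type
thioesterase (MbL-TE), a TE-less nonreducing polyketide synthase whose
domain string is SAT-KS-AT-(PT)-ACP, and a small EthD-domain gene — in a
conserved order. Candidate families are found through reference clusters
linked to anthraquinones or structurally related compounds (emodin,
asperthecin, endocrocin, clavorubin, alternariol, TAN-1612); each candidate
cluster is then classified against the four-gene template, with named
variants for the naturally occurring exceptions (missing EthD, missing
ABC-transporter, PKS-only, EthD domain absorbed into the PKS gene).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .bgcnet import ClusterRecord, FamilyAssignment, GeneRecord

__all__ = [
    "Role",
    "Variant",
    "RoleLexicon",
    "ArchitectureReport",
    "ScreenSummary",
    "DEFAULT_COMPOUNDS",
    "default_lexicon",
    "find_reference_families",
    "check_pks_domain_order",
    "classify_architecture",
    "screen_genomes",
]


class Role(str, Enum):
    ABC_TRANSPORTER = "ABC_TRANSPORTER"
    MBL_TE = "MBL_TE"
    NR_PKS = "NR_PKS"
    ETHD = "ETHD"
    OTHER = "OTHER"


class Variant(str, Enum):
    COMPLETE = "COMPLETE"
    MISSING_ETHD = "MISSING_ETHD"
    MISSING_ABC = "MISSING_ABC"
    PKS_ONLY = "PKS_ONLY"
    ETHD_IN_PKS = "ETHD_IN_PKS"
    OTHER_PARTIAL = "OTHER_PARTIAL"
    NOT_CANDIDATE = "NOT_CANDIDATE"


#: compounds whose reference clusters mark candidate anthraquinone families
DEFAULT_COMPOUNDS = frozenset(
    {"emodin", "asperthecin", "endocrocin", "clavorubin", "alternariol", "TAN-1612"}
)

PKS_DOMAINS = ("SAT", "KS", "AT", "PT", "ACP", "TE")
CORE_PKS_ORDER = ("SAT", "KS", "AT", "ACP")  # PT optional: often missed by annotation


@dataclass
class RoleLexicon:
    """Maps domain labels and gene role annotations onto screen roles."""

    label_to_role: dict[str, Role]
    pks_domains: tuple[str, ...] = PKS_DOMAINS

    def role_of_label(self, label: str) -> Role:
        return self.label_to_role.get(label, Role.OTHER)


def default_lexicon() -> RoleLexicon:
    mapping = {
        "ABC_transporter": Role.ABC_TRANSPORTER,
        "ABC_membrane": Role.ABC_TRANSPORTER,
        "ABC_tran": Role.ABC_TRANSPORTER,
        "MBL_TE": Role.MBL_TE,
        "Metallo-beta-lactamase": Role.MBL_TE,
        "Lactamase_B": Role.MBL_TE,
        "EthD": Role.ETHD,
    }
    return RoleLexicon(label_to_role=mapping)


@dataclass(frozen=True)
class ArchitectureReport:
    cluster_id: str
    genome_id: str
    roles_present: frozenset[Role]
    pks_domain_order_ok: bool
    pks_te_less: bool
    ethd_in_pks: bool
    order_matched: bool
    variant: Variant
    extra_genes: tuple[str, ...] = ()


@dataclass
class ScreenSummary:
    candidate_families: list[str]
    reports: list[ArchitectureReport]
    clade_of: dict[str, str]

    def candidates_per_genome(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for r in self.reports:
            out.setdefault(r.genome_id, []).append(r.cluster_id)
        return {k: sorted(v) for k, v in out.items()}

    def role_incidence(self) -> dict[Role, set[str]]:
        """Role -> set of clades in which the role occurs among candidates."""
        inc: dict[Role, set[str]] = {r: set() for r in Role if r is not Role.OTHER}
        for rep in self.reports:
            clade = self.clade_of.get(rep.genome_id)
            if clade is None:
                continue
            for role in rep.roles_present:
                if role is not Role.OTHER:
                    inc[role].add(clade)
        return inc

    def exclusivity(self) -> dict[Role, str | None]:
        """Role -> the single clade it is confined to, or None if not exclusive."""
        out: dict[Role, str | None] = {}
        for role, clades in self.role_incidence().items():
            out[role] = next(iter(clades)) if len(clades) == 1 else None
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                r.cluster_id,
                r.genome_id,
                self.clade_of.get(r.genome_id, ""),
                ";".join(sorted(x.value for x in r.roles_present)),
                r.pks_domain_order_ok,
                r.pks_te_less,
                r.ethd_in_pks,
                r.order_matched,
                r.variant.value,
                ";".join(r.extra_genes),
            )
            for r in self.reports
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "cluster_id",
                "genome_id",
                "clade",
                "roles_present",
                "pks_domain_order_ok",
                "pks_te_less",
                "ethd_in_pks",
                "order_matched",
                "variant",
                "extra_genes",
            ],
        )


# ---------------------------------------------------------------------------


def variant_fixtures() -> dict[Variant, ClusterRecord]:
    """Synthetic clusters instantiating the naturally observed variants.

    One cluster per named variant of the four-gene architecture, modelled on
    the exceptions seen across Teloschistales genomes: the full complement
    (Variospora-like), a missing EthD gene (Seirophora-like), a missing
    ABC-transporter (Xanthoria-like), the core PKS alone (Caloplaca-like),
    and the EthD domain absorbed into the PKS gene (Usnochroma-like).
    """

    def mk(cid: str, genome: str, genes: list[tuple[str, list[str]]]) -> ClusterRecord:
        return ClusterRecord(
            cluster_id=cid,
            genome_id=genome,
            bgc_class="PKSI",
            genes=[
                GeneRecord(f"{cid}|g{k}", k, "+", role, list(doms), "MK" + "A" * 40)
                for k, (role, doms) in enumerate(genes)
            ],
        )

    abc = ("ABC_transporter", ["ABC_tran", "ABC_membrane"])
    mbl = ("MBL_TE", ["Lactamase_B"])
    pks = ("PKS", ["SAT", "KS", "AT", "PT", "ACP"])
    pks_ethd = ("PKS", ["SAT", "KS", "AT", "PT", "ACP", "EthD"])
    ethd = ("EthD", ["EthD"])
    return {
        Variant.COMPLETE: mk("fix_complete", "Variospora_like", [abc, mbl, pks, ethd]),
        Variant.MISSING_ETHD: mk("fix_no_ethd", "Seirophora_like", [abc, mbl, pks]),
        Variant.MISSING_ABC: mk("fix_no_abc", "Xanthoria_like", [mbl, pks, ethd]),
        Variant.PKS_ONLY: mk("fix_pks_only", "Caloplaca_like", [pks]),
        Variant.ETHD_IN_PKS: mk("fix_ethd_in_pks", "Usnochroma_like", [abc, mbl, pks_ethd]),
    }


def find_reference_families(
    assignment: FamilyAssignment, compound_set=DEFAULT_COMPOUNDS
) -> tuple[list[str], list[ClusterRecord]]:
    """Families containing a reference cluster for a listed compound.

    Returns (flagged family ids, all member clusters of those families as
    screening candidates, references excluded).
    """
    refs = [c for c in assignment.clusters.values() if c.is_reference]
    if not refs:
        raise ValueError("assignment contains no reference clusters")
    compound_set = set(compound_set)
    flagged: list[str] = []
    for fam, members in sorted(assignment.families().items()):
        for m in members:
            c = assignment.clusters[m]
            if c.is_reference and c.compound in compound_set:
                flagged.append(fam)
                break
    candidates = [
        assignment.clusters[m]
        for fam in flagged
        for m in assignment.families()[fam]
        if not assignment.clusters[m].is_reference
    ]
    return flagged, candidates


def _is_subsequence(needle, haystack) -> bool:
    it = iter(haystack)
    return all(x in it for x in needle)


def check_pks_domain_order(
    gene: GeneRecord, lexicon: RoleLexicon | None = None
) -> tuple[bool, bool, bool]:
    """(order_ok, te_less, ethd_in_pks) for a putative PKS gene.

    order_ok: SAT, KS, AT, ACP appear as an order-preserving subsequence of the
    gene's domains (other domains, including PT, may intervene); te_less: no TE
    domain; ethd_in_pks: an EthD-mapped domain sits inside the gene.
    """
    lexicon = lexicon or default_lexicon()
    doms = list(gene.domains)
    order_ok = _is_subsequence(CORE_PKS_ORDER, doms) or _is_subsequence(
        CORE_PKS_ORDER, doms[::-1]
    )
    te_less = "TE" not in doms
    ethd = any(lexicon.role_of_label(d) is Role.ETHD for d in doms)
    return order_ok, te_less, ethd


def _gene_role(gene: GeneRecord, lexicon: RoleLexicon) -> Role:
    if "KS" in gene.domains and "AT" in gene.domains:
        return Role.NR_PKS
    for candidate in [gene.role_annotation, *gene.domains]:
        role = lexicon.role_of_label(candidate)
        if role is not Role.OTHER:
            return role
    return Role.OTHER


def classify_architecture(
    cluster: ClusterRecord, lexicon: RoleLexicon | None = None
) -> ArchitectureReport:
    """Classify one cluster against the four-gene anthraquinone template.

    The canonical order is (ABC-transporter, MbL-TE, NR-PKS, EthD); it is
    accepted in either strand orientation and tolerates intervening genes.
    """
    lexicon = lexicon or default_lexicon()
    if not cluster.genes:
        raise ValueError(f"cluster {cluster.cluster_id!r} has no genes")
    roles = [_gene_role(g, lexicon) for g in cluster.genes]
    present = frozenset(r for r in roles if r is not Role.OTHER)
    extra = tuple(
        g.gene_id for g, r in zip(cluster.genes, roles) if r is Role.OTHER
    )

    pks_genes = [g for g, r in zip(cluster.genes, roles) if r is Role.NR_PKS]
    order_ok = te_less = ethd_in = False
    for g in pks_genes:
        ok, te, ei = check_pks_domain_order(g, lexicon)
        order_ok = order_ok or ok
        te_less = te_less or te
        ethd_in = ethd_in or ei

    canonical = (Role.ABC_TRANSPORTER, Role.MBL_TE, Role.NR_PKS, Role.ETHD)
    informative = [r for r in roles if r is not Role.OTHER]
    order_matched = _is_subsequence(canonical, informative) or _is_subsequence(
        canonical, informative[::-1]
    )

    four = {Role.ABC_TRANSPORTER, Role.MBL_TE, Role.NR_PKS, Role.ETHD}
    if Role.NR_PKS not in present:
        variant = Variant.NOT_CANDIDATE
    elif present >= four and order_matched:
        variant = Variant.COMPLETE
    elif present >= {Role.ABC_TRANSPORTER, Role.MBL_TE, Role.NR_PKS} and (
        Role.ETHD not in present
    ):
        variant = Variant.ETHD_IN_PKS if ethd_in else Variant.MISSING_ETHD
    elif present >= {Role.MBL_TE, Role.NR_PKS, Role.ETHD} and (
        Role.ABC_TRANSPORTER not in present
    ):
        variant = Variant.MISSING_ABC
    elif present & four == {Role.NR_PKS}:
        variant = Variant.PKS_ONLY
    else:
        variant = Variant.OTHER_PARTIAL

    return ArchitectureReport(
        cluster_id=cluster.cluster_id,
        genome_id=cluster.genome_id,
        roles_present=present,
        pks_domain_order_ok=order_ok,
        pks_te_less=te_less,
        ethd_in_pks=ethd_in,
        order_matched=order_matched,
        variant=variant,
        extra_genes=extra,
    )


def screen_genomes(
    assignment: FamilyAssignment,
    clade_map: dict[str, str],
    lexicon: RoleLexicon | None = None,
    compound_set=DEFAULT_COMPOUNDS,
) -> ScreenSummary:
    """Full screen: flag reference families, classify candidates, summarize clades."""
    lexicon = lexicon or default_lexicon()
    genomes = {
        c.genome_id for c in assignment.clusters.values() if not c.is_reference
    }
    missing = genomes - set(clade_map)
    if missing:
        raise ValueError(f"clade map missing genomes: {sorted(missing)}")
    flagged, candidates = find_reference_families(assignment, compound_set)
    reports = [classify_architecture(c, lexicon) for c in candidates]
    return ScreenSummary(
        candidate_families=flagged, reports=reports, clade_of=dict(clade_map)
    )
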