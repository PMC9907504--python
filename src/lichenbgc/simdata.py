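"""Synthetic lichen-metagenome, BGC-panel, and tree/presence-absence generators.

Everything downstream of real sequencing — binning, gene-cluster networking,
diversity statistics, architecture screening — is exercised against data from
this module, which carries complete ground truth. Three generators:

* :func:`simulate_metagenome` emits contigs for a community of organisms, each
  with its own order-2 Markov compositional signature calibrated to a target
  GC, lognormal per-contig coverage, and a taxonomy table with tunable no-hit
  rates. The default community reproduces the situation this toolkit targets:
  a fungal mycobiont forming a "linear cloud" at 30-50% GC with consistent
  coverage, including an AT-rich tail whose contigs mostly lack database hits,
  plus a green-algal photobiont and two bacteria at distinct GC/coverage.
* :func:`simulate_bgc_panel` derives per-genome gene-cluster instances from
  family archetypes by gene loss, domain shuffling, and residue divergence,
  emitting reference (MIBiG-like) clusters unmutated with their compounds.
* :func:`simulate_tree_and_pa` grows a Yule tree and evolves binary
  family-presence columns along it under a two-state gain/loss Markov process,
  giving matrices with tunable phylogenetic signal.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._markov import MarkovSequenceModel
from .bgcnet import ClusterRecord, GeneRecord

__all__ = [
    "OrganismSpec",
    "ArchetypeSpec",
    "EvolutionParams",
    "ROLES",
    "DOMAIN_LEXICON",
    "AMINO_ACIDS",
    "default_community",
    "simulate_metagenome",
    "random_archetypes",
    "anthraquinone_archetypes",
    "simulate_bgc_panel",
    "simulate_tree_and_pa",
]

ROLES = ("mycobiont_core", "mycobiont_at_tail", "photobiont", "bacterium")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: declared domain vocabulary for archetypes and mutated instances
DOMAIN_LEXICON = (
    "SAT", "KS", "AT", "PT", "ACP", "TE",  # nonreducing PKS
    "KR", "DH", "ER", "MT",                # reducing PKS tailoring
    "C", "A", "PCP", "E",                  # NRPS
    "TC", "P450", "FAD_ox", "OMT", "GT", "SDR",
    "ABC_tran", "ABC_membrane", "MFS", "Lactamase_B", "EthD",
    "Zn_clus", "Fungal_trans", "Aminotran", "Epimerase", "Acyl_CoA_lig",
)


@dataclass(frozen=True)
class OrganismSpec:
    """One community member of a simulated lichen metagenome."""

    name: str
    role: str
    genome_size: int
    gc_mean: float
    gc_sd: float
    coverage_mean: float
    coverage_sd_log: float
    taxon_label: str
    label_miss_prob: float
    markov_seed: int

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if not (0.0 < self.gc_mean - 3 * self.gc_sd and self.gc_mean + 3 * self.gc_sd < 1.0):
            raise ValueError(
                f"{self.name}: gc_mean +/- 3*gc_sd must stay inside (0, 1)"
            )
        if self.coverage_mean <= 0:
            raise ValueError(f"{self.name}: coverage_mean must be positive")
        if not 0.0 <= self.label_miss_prob <= 1.0:
            raise ValueError(f"{self.name}: label_miss_prob outside [0, 1]")


def default_community() -> list[OrganismSpec]:
    """The default simulated lichen community.

    A ~5 Mbp mycobiont core at GC 0.50 with an AT-rich tail carrying 20% of
    the mycobiont bases at GC 0.33 and 80% missing taxonomy labels; a
    green-algal photobiont at GC 0.60 and distinct coverage; and two bacteria
    separated in both GC and coverage.
    """
    return [
        OrganismSpec("mycobiont_core", "mycobiont_core", 5_000_000, 0.50, 0.02,
                     30.0, 0.25, "Ascomycota", 0.30, markov_seed=101),
        OrganismSpec("mycobiont_tail", "mycobiont_at_tail", 1_250_000, 0.33, 0.02,
                     30.0, 0.25, "Ascomycota", 0.80, markov_seed=101),
        OrganismSpec("photobiont", "photobiont", 3_000_000, 0.60, 0.02,
                     90.0, 0.25, "Chlorophyta", 0.20, markov_seed=202),
        OrganismSpec("bacterium_1", "bacterium", 2_000_000, 0.42, 0.02,
                     150.0, 0.25, "Proteobacteria", 0.20, markov_seed=303),
        OrganismSpec("bacterium_2", "bacterium", 2_000_000, 0.66, 0.02,
                     7.0, 0.25, "Actinobacteria", 0.20, markov_seed=404),
    ]


def simulate_metagenome(
    specs: list[OrganismSpec],
    contig_length_dist: tuple[int, int] = (5_000, 20_000),
    seed: int = 0,
):
    """Emit a synthetic metagenome: contigs, coverage, taxonomy, and truth.

    Returns ``(contigs, coverage, taxonomy, truth)`` where contigs is a dict
    id -> sequence, coverage a DataFrame (contig_id, mean_depth), taxonomy a
    DataFrame (contig_id, taxon, rank, bitscore, evalue, tier) in which a
    contig is absent with its organism's ``label_miss_prob`` ("no hit"), and
    truth a DataFrame mapping every contig to its organism, role, realized GC
    and coverage.
    """
    if not specs:
        raise ValueError("no organisms")
    min_len, mean_len = contig_length_dist
    if min_len < 1 or mean_len < min_len:
        raise ValueError("contig_length_dist must satisfy 1 <= min <= mean")
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    cov_rows, tax_rows, truth_rows = [], [], []
    counter = 0
    for spec in specs:
        model = MarkovSequenceModel(spec.markov_seed)
        emitted = 0
        while emitted < spec.genome_size:
            if mean_len > min_len:
                length = min_len + int(rng.geometric(1.0 / (mean_len - min_len))) - 1
            else:
                length = min_len
            counter += 1
            cid = f"contig_{counter:05d}"
            target_gc = float(
                np.clip(rng.normal(spec.gc_mean, spec.gc_sd), 0.02, 0.98)
            )
            seq = model.sample(length, target_gc, rng)
            contigs[cid] = seq
            emitted += length
            depth = float(rng.lognormal(np.log(spec.coverage_mean), spec.coverage_sd_log))
            cov_rows.append((cid, depth))
            gc = (seq.count("G") + seq.count("C")) / length
            truth_rows.append((cid, spec.name, spec.role, gc, depth))
            if rng.random() >= spec.label_miss_prob:
                bits = float(rng.uniform(150, 450))
                tax_rows.append(
                    (cid, spec.taxon_label, "phylum", bits,
                     float(10.0 ** rng.uniform(-60, -30)), "protein")
                )
                if rng.random() < 0.5:  # second hit tier for the same phylum
                    tax_rows.append(
                        (cid, spec.taxon_label, "phylum", float(rng.uniform(80, 250)),
                         float(10.0 ** rng.uniform(-50, -26)), "nucleotide")
                    )
    coverage = pd.DataFrame(cov_rows, columns=["contig_id", "mean_depth"])
    taxonomy = pd.DataFrame(
        tax_rows, columns=["contig_id", "taxon", "rank", "bitscore", "evalue", "tier"]
    )
    truth = pd.DataFrame(
        truth_rows, columns=["contig_id", "organism", "role", "gc", "coverage"]
    )
    return contigs, coverage, taxonomy, truth


# ---------------------------------------------------------------------------
# BGC panels


@dataclass(frozen=True)
class ArchetypeSpec:
    """A family archetype from which per-genome cluster instances are derived.

    ``clades=None`` puts the archetype in every genome; an explicit tuple
    restricts it to genomes of those clades (empty tuple: reference-only).
    ``is_reference`` additionally emits one unmutated, compound-annotated
    MIBiG-like copy.
    """

    family_id: str
    bgc_class: str = "PKSI"
    genes: tuple[tuple[str, tuple[str, ...], str], ...] = ()
    is_reference: bool = False
    compound: str | None = None
    clades: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"archetype {self.family_id!r} has no genes")
        for _, domains, _ in self.genes:
            for d in domains:
                if d not in DOMAIN_LEXICON:
                    raise ValueError(f"domain {d!r} not in the declared lexicon")


@dataclass(frozen=True)
class EvolutionParams:
    gene_loss_prob: float = 0.1
    domain_swap_prob: float = 0.1
    residue_sub_prob: float = 0.1
    gain_rate: float = 1.0
    loss_rate: float = 1.0
    n_tips: int = 20
    n_families: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.gene_loss_prob, self.domain_swap_prob, self.residue_sub_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("mutation probabilities must lie in [0, 1]")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("gain/loss rates must be non-negative")
        if self.n_tips < 3:
            raise ValueError("n_tips must be at least 3")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def random_archetypes(
    n_families: int = 20,
    seed: int = 0,
    classes: tuple[str, ...] = ("PKSI", "NRPS", "Terpene"),
    genes_range: tuple[int, int] = (4, 7),
    domains_range: tuple[int, int] = (2, 4),
    sublexicon_size: int = 6,
    seq_len_range: tuple[int, int] = (100, 200),
) -> list[ArchetypeSpec]:
    """Random, mutually distant family archetypes for recovery experiments.

    Each family draws its genes' domains from a small family-specific
    sub-lexicon, mimicking how real clusters reuse a handful of domain types
    (multiple P450s, repeated PKS modules) rather than sampling the whole
    vocabulary uniformly.
    """
    rng = np.random.default_rng(seed)
    roles = ("biosynthetic", "transport", "tailoring", "regulatory")
    out = []
    for i in range(n_families):
        sub = rng.choice(DOMAIN_LEXICON, size=sublexicon_size, replace=False)
        n_genes = int(rng.integers(genes_range[0], genes_range[1] + 1))
        genes = []
        for j in range(n_genes):
            n_dom = int(rng.integers(domains_range[0], domains_range[1] + 1))
            domains = tuple(rng.choice(sub, size=n_dom, replace=True))
            seq = _random_sequence(
                rng, int(rng.integers(seq_len_range[0], seq_len_range[1] + 1))
            )
            genes.append((str(rng.choice(roles)), domains, seq))
        out.append(
            ArchetypeSpec(
                family_id=f"fam_{i:03d}",
                bgc_class=str(classes[i % len(classes)]),
                genes=tuple(genes),
            )
        )
    return out


def anthraquinone_archetypes(seed: int = 7) -> list[ArchetypeSpec]:
    """Archetypes instantiating the four-gene anthraquinone architecture.

    One Teloschistales-restricted archetype carries the full
    ABC-transporter / MbL-TE / NR-PKS / EthD gene order and doubles as an
    asperthecin reference; a second, unrestricted archetype carries only the
    PKS and EthD genes (the non-Teloschistales situation); a melanin-like
    reference archetype provides a non-anthraquinone control family.
    """
    rng = np.random.default_rng(seed)
    s = lambda n: _random_sequence(rng, n)  # noqa: E731
    pks_seq, ethd_seq = s(150), s(60)

    def diverged(seq: str, rate: float = 0.12) -> str:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        hit = rng.random(arr.size) < rate
        aas = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
        arr[hit] = aas[rng.integers(0, len(aas), size=int(hit.sum()))]
        return arr.tobytes().decode()

    telo = ArchetypeSpec(
        family_id="AQ_telo",
        bgc_class="PKSI",
        genes=(
            ("ABC_transporter", ("ABC_tran", "ABC_membrane"), s(90)),
            ("MBL_TE", ("Lactamase_B",), s(80)),
            ("PKS", ("SAT", "KS", "AT", "ACP"), pks_seq),
            ("EthD", ("EthD",), ethd_seq),
        ),
        is_reference=True,
        compound="asperthecin",
        clades=("Teloschistales",),
    )
    # structurally related cluster: same core genes, moderately diverged
    broad = ArchetypeSpec(
        family_id="AQ_broad",
        bgc_class="PKSI",
        genes=(
            ("PKS", ("SAT", "KS", "AT", "ACP"), diverged(pks_seq)),
            ("EthD", ("EthD",), diverged(ethd_seq)),
        ),
        is_reference=True,
        compound="emodin",
        clades=None,
    )
    control = ArchetypeSpec(
        family_id="melanin_ctrl",
        bgc_class="PKSI",
        genes=(
            ("PKS", ("SAT", "KS", "AT", "PT", "ACP", "TE"), s(150)),
            ("tailoring", ("P450",), s(80)),
        ),
        is_reference=True,
        compound="melanin",
        clades=None,
    )
    return [telo, broad, control]


def _mutate_gene(
    role: str,
    domains: tuple[str, ...],
    seq: str,
    params: EvolutionParams,
    rng: np.random.Generator,
) -> tuple[str, list[str], str]:
    # domain shuffling: each domain is transposed with its neighbour with
    # probability domain_swap_prob, perturbing order but not content
    new_domains = list(domains)
    for i in range(len(new_domains)):
        if rng.random() < params.domain_swap_prob:
            j = i + 1 if i + 1 < len(new_domains) else i - 1
            if j >= 0:
                new_domains[i], new_domains[j] = new_domains[j], new_domains[i]
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < params.residue_sub_prob
    if hit.any():
        aas = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
        repl = aas[rng.integers(0, len(aas) - 1, size=int(hit.sum()))]
        cur = arr[hit]
        # substitute with a residue different from the current one
        same = repl == cur
        repl[same] = aas[(np.searchsorted(aas, cur[same]) + 1) % len(aas)]
        arr[hit] = repl
    return role, new_domains, arr.tobytes().decode()


def simulate_bgc_panel(
    archetypes: list[ArchetypeSpec],
    genome_clade_map: dict[str, str],
    params: EvolutionParams,
    seed: int | None = None,
    genomes: list[str] | None = None,
):
    """Derive per-genome cluster instances from archetypes, with truth labels.

    Returns ``(clusters, truth)``: ``clusters`` is a list of ClusterRecord
    (reference archetypes additionally emitted unmutated with their compound),
    ``truth`` a DataFrame (cluster_id, genome_id, family_id, status) where
    status is "present", "reference", or "lost" (all genes dropped).
    """
    if not archetypes:
        raise ValueError("no archetypes")
    if genomes is None:
        genomes = sorted(genome_clade_map)
    unknown = [g for g in genomes if g not in genome_clade_map]
    if unknown:
        raise ValueError(f"genomes missing from clade map: {unknown}")
    known_clades = set(genome_clade_map.values())
    if genome_clade_map:
        for a in archetypes:
            if a.clades:
                bad = set(a.clades) - known_clades
                if bad:
                    raise ValueError(
                        f"archetype {a.family_id!r} restricted to unknown clades "
                        f"{sorted(bad)}"
                    )
    rng = np.random.default_rng(params.seed if seed is None else seed)
    clusters: list[ClusterRecord] = []
    truth_rows = []
    for arch in archetypes:
        if arch.is_reference:
            cid = f"REF|{arch.family_id}"
            clusters.append(
                ClusterRecord(
                    cluster_id=cid,
                    genome_id="MIBiG",
                    bgc_class=arch.bgc_class,
                    genes=[
                        GeneRecord(f"{cid}|g{k}", k, "+", role, list(dom), seq)
                        for k, (role, dom, seq) in enumerate(arch.genes)
                    ],
                    is_reference=True,
                    compound=arch.compound,
                )
            )
            truth_rows.append((cid, "MIBiG", arch.family_id, "reference"))
    for genome in genomes:
        clade = genome_clade_map[genome]
        for arch in archetypes:
            if arch.clades is not None and clade not in arch.clades:
                continue
            cid = f"{genome}|{arch.family_id}"
            kept = []
            for k, (role, dom, seq) in enumerate(arch.genes):
                if rng.random() < params.gene_loss_prob:
                    continue
                role2, dom2, seq2 = _mutate_gene(role, dom, seq, params, rng)
                kept.append(
                    GeneRecord(f"{cid}|g{k}", len(kept), "+", role2, dom2, seq2)
                )
            if not kept:
                truth_rows.append((cid, genome, arch.family_id, "lost"))
                continue
            clusters.append(
                ClusterRecord(
                    cluster_id=cid,
                    genome_id=genome,
                    bgc_class=arch.bgc_class,
                    genes=kept,
                )
            )
            truth_rows.append((cid, genome, arch.family_id, "present"))
    truth = pd.DataFrame(
        truth_rows, columns=["cluster_id", "genome_id", "family_id", "status"]
    )
    return clusters, truth


# ---------------------------------------------------------------------------
# trees and presence-absence evolution


class _Node:
    __slots__ = ("children", "length", "name")

    def __init__(self, length: float = 0.0):
        self.children: list[_Node] = []
        self.length = length
        self.name: str | None = None


def _yule_tree(n_tips: int, rng: np.random.Generator) -> _Node:
    """Pure-birth tree, unit speciation rate, total depth set by the process."""
    root = _Node(0.0)
    tips = []
    for _ in range(2):
        c = _Node(0.0)
        root.children.append(c)
        tips.append(c)
    while len(tips) < n_tips:
        dt = rng.exponential(1.0 / len(tips))
        for t in tips:
            t.length += dt
        idx = int(rng.integers(len(tips)))
        parent = tips.pop(idx)
        for _ in range(2):
            c = _Node(0.0)
            parent.children.append(c)
            tips.append(c)
    dt = rng.exponential(1.0 / len(tips))
    for t in tips:
        t.length += dt
    i = 0
    stack = [root]
    while stack:  # preorder tip naming, deterministic
        node = stack.pop()
        if not node.children:
            i += 1
            node.name = f"T{i:03d}"
        else:
            stack.extend(reversed(node.children))
    return root


def _newick(node: _Node) -> str:
    if not node.children:
        return f"{node.name}:{node.length:.8f}"
    inner = ",".join(_newick(c) for c in node.children)
    return f"({inner}):{node.length:.8f}"


def simulate_tree_and_pa(params: EvolutionParams):
    """Yule tree plus binary family columns evolved by a gain/loss process.

    Each of ``n_families`` columns starts at the root in the stationary state
    of the two-state Markov chain (gain rate g, loss rate l) and transitions
    along each branch of length t with P(0->1) = pi1 * (1 - exp(-(g+l) t)),
    P(1->1) = pi1 + (1 - pi1) * exp(-(g+l) t), pi1 = g / (g + l).

    Returns ``(newick, pa, root_states)`` with pa a tips x families 0/1
    DataFrame.
    """
    rng = np.random.default_rng(params.seed)
    root = _yule_tree(params.n_tips, rng)
    newick = _newick(root).rsplit(":", 1)[0] + ";"

    g, l = params.gain_rate, params.loss_rate
    total = g + l
    nf = params.n_families
    if total > 0:
        pi1 = g / total
        root_states = (rng.random(nf) < pi1).astype(np.int8)
    else:
        pi1 = 0.0
        root_states = np.zeros(nf, dtype=np.int8)
        warnings.warn(
            "gain and loss rates are both zero with absent root states: "
            "all-zero presence-absence columns"
        )

    rows: dict[str, np.ndarray] = {}

    def descend(node: _Node, state: np.ndarray) -> None:
        if node is not root:
            if total > 0:
                decay = np.exp(-total * node.length)
                p1 = np.where(state == 1, pi1 + (1 - pi1) * decay, pi1 * (1 - decay))
                state = (rng.random(nf) < p1).astype(np.int8)
            else:
                state = state.copy()
        if not node.children:
            rows[node.name] = state
            return
        for c in node.children:
            descend(c, state)

    descend(root, root_states)
    tips = sorted(rows)
    pa = pd.DataFrame(
        np.vstack([rows[t] for t in tips]),
        index=tips,
        columns=[f"fam_{j:04d}" for j in range(nf)],
        dtype=int,
    )
    return newick, pa, root_states
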