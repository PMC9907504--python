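"""Mycobiont genome isolation from metagenomic contigs.

The pipeline combines composition/coverage clustering with taxonomy, the way
lichen metagenome studies separate the fungal symbiont from its photobiont
and bacterial cohabitants:

1. per-contig features: GC, canonical tetranucleotide profile, read depth;
2. taxonomy calls from tabulated BLAST-style hits (e-value cutoff 1e-25,
   summed bitscore per phylum across protein and nucleotide tiers);
3. contigs are cut into 10 kbp fragments, embedded by PCA of the
   tetranucleotide profile plus standardized log10 depth, and clustered with
   Gaussian mixtures, the component count chosen by BIC;
4. the anchor bin is the one holding the most target-taxon (Ascomycota)
   bases; low-GC "tail" bins with consistent coverage and few foreign-taxon
   bases are merged into it — this recovers the AT-rich tail of the mycobiont
   cloud even when its contigs have no database hits;
5. contigs whose call is neither the target taxon nor NO_HIT are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

__all__ = [
    "NO_HIT",
    "N_CANONICAL_KMERS",
    "ContigRecord",
    "TaxonomyConfig",
    "Bin",
    "BinningConfig",
    "compute_contig_features",
    "assign_taxonomy",
    "fragment_contigs",
    "cluster_fragments",
    "select_anchor_bin",
    "merge_tail_bins",
    "filter_contaminants",
    "run_binning",
]

NO_HIT = "NO_HIT"

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i


def _canonical_kmer_map(k: int = 4) -> tuple[np.ndarray, int]:
    """Map every k-mer code to a canonical index (min of self and revcomp)."""
    n = 4**k
    codes = np.arange(n)
    rc = np.zeros(n, dtype=np.int64)
    tmp = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - tmp % 4)
        tmp //= 4
    canon = np.minimum(codes, rc)
    uniq, idx = np.unique(canon, return_inverse=True)
    return idx, len(uniq)


_CANON_IDX, N_CANONICAL_KMERS = _canonical_kmer_map(4)  # 136 canonical 4-mers


@dataclass
class ContigRecord:
    contig_id: str
    length: int
    gc: float
    coverage: float
    kmer_profile: np.ndarray
    taxon_call: str = NO_HIT


@dataclass(frozen=True)
class TaxonomyConfig:
    evalue_cutoff: float = 1e-25
    rank: str = "phylum"
    target_taxon: str = "Ascomycota"

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")


@dataclass
class Bin:
    bin_id: int
    members: list[str]
    total_bp: int
    median_gc: float
    median_coverage: float
    taxon_bp_fraction: dict[str, float]


@dataclass(frozen=True)
class BinningConfig:
    fragment_size: int = 10_000
    max_bins: int = 10
    coverage_ratio_tol: float = 2.0
    gc_slack: float = 0.02
    contaminant_bp_frac: float = 0.2
    pca_variance: float = 0.90
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fragment_size < 1000:
            raise ValueError("fragment_size must be at least 1000")
        if self.coverage_ratio_tol < 1:
            raise ValueError("coverage_ratio_tol must be >= 1")


# ---------------------------------------------------------------------------
# features


def _gc_and_profile(seq: str) -> tuple[float, np.ndarray, np.ndarray]:
    arr = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    valid = arr >= 0
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("sequence has no unambiguous bases")
    gc = float(np.isin(arr, (1, 2)).sum() / n_valid)
    counts = np.zeros(N_CANONICAL_KMERS, dtype=np.float64)
    if arr.size >= 4:
        codes = (
            arr[:-3] * 64 + arr[1:-2] * 16 + arr[2:-1] * 4 + arr[3:]
        )
        ok = valid[:-3] & valid[1:-2] & valid[2:-1] & valid[3:]
        if ok.any():
            counts += np.bincount(
                _CANON_IDX[codes[ok]], minlength=N_CANONICAL_KMERS
            )
    counts += 1.0  # pseudocount
    return gc, counts / counts.sum(), arr


def compute_contig_features(
    contigs: dict[str, str], coverage: pd.DataFrame
) -> dict[str, ContigRecord]:
    """GC, canonical 4-mer profile (+1 pseudocount), and depth per contig."""
    cov = dict(zip(coverage["contig_id"], coverage["mean_depth"]))
    missing = [cid for cid in contigs if cid not in cov]
    if missing:
        raise ValueError(f"contigs without coverage rows: {sorted(missing)}")
    out: dict[str, ContigRecord] = {}
    for cid, seq in contigs.items():
        if not seq:
            raise ValueError(f"contig {cid!r} has an empty sequence")
        gc, profile, _ = _gc_and_profile(seq)
        out[cid] = ContigRecord(
            contig_id=cid,
            length=len(seq),
            gc=gc,
            coverage=float(cov[cid]),
            kmer_profile=profile,
        )
    return out


def assign_taxonomy(
    hits: pd.DataFrame, config: TaxonomyConfig | None = None
) -> dict[str, str]:
    """Best-sum taxonomy call per contig.

    Hits above the e-value cutoff are discarded; surviving bitscores are
    summed per taxon across both hit tiers and the top-scoring taxon wins,
    ties broken lexicographically. Contigs with no surviving rows simply do
    not appear in the result (callers treat them as NO_HIT).
    """
    config = config or TaxonomyConfig()
    if hits.empty:
        return {}
    if (hits["bitscore"] < 0).any():
        raise ValueError("negative bitscore in hit table")
    kept = hits[hits["evalue"] <= config.evalue_cutoff]
    if kept.empty:
        return {}
    summed = (
        kept.groupby(["contig_id", "taxon"])["bitscore"].sum().reset_index()
    )
    summed = summed.sort_values(
        ["contig_id", "bitscore", "taxon"], ascending=[True, False, True]
    )
    best = summed.drop_duplicates("contig_id", keep="first")
    return dict(zip(best["contig_id"], best["taxon"]))


# ---------------------------------------------------------------------------
# fragmentation and clustering


def fragment_contigs(
    contigs: dict[str, str], fragment_size: int = 10_000
) -> pd.DataFrame:
    """Cut contigs into consecutive windows (0-based half-open coordinates).

    A terminal remainder shorter than ``fragment_size`` is appended to the
    preceding window; contigs shorter than the window form one fragment.
    """
    rows = []
    for cid in contigs:
        length = len(contigs[cid])
        n_full = length // fragment_size
        if n_full <= 1:
            bounds = [(0, length)]
        else:
            bounds = [
                (i * fragment_size, (i + 1) * fragment_size)
                for i in range(n_full - 1)
            ]
            bounds.append(((n_full - 1) * fragment_size, length))
        for k, (s, e) in enumerate(bounds):
            rows.append((f"{cid}|f{k:03d}", cid, s, e))
    return pd.DataFrame(rows, columns=["fragment_id", "parent_id", "start", "end"])


def cluster_fragments(
    contigs: dict[str, str],
    records: dict[str, ContigRecord],
    fragments: pd.DataFrame,
    config: BinningConfig | None = None,
) -> tuple[pd.Series, dict[str, int], dict] :
    """Cluster fragments on composition + depth; vote contigs into bins.

    Fragments are embedded by PCA (retaining >= ``pca_variance`` of variance)
    of their canonical 4-mer profile concatenated with standardized
    log10(depth + 1), then fit with Gaussian mixtures for k = 1..max_bins;
    k is chosen by BIC. A contig's bin is the label holding the largest summed
    fragment length (ties to the lower label).

    Returns (per-fragment labels, per-contig labels, model report).
    """
    config = config or BinningConfig()
    frags = fragments.sort_values("fragment_id").reset_index(drop=True)
    n = len(frags)
    if n < 2:
        warnings.warn("fewer than 2 fragments: single bin")
        labels = pd.Series(0, index=frags["fragment_id"])
        return labels, {p: 0 for p in frags["parent_id"]}, {"k": 1, "bic": {}}
    profiles = np.empty((n, N_CANONICAL_KMERS))
    logcov = np.empty(n)
    for i, row in enumerate(frags.itertuples(index=False)):
        seq = contigs[row.parent_id][row.start : row.end]
        _, profile, _ = _gc_and_profile(seq)
        profiles[i] = profile
        logcov[i] = np.log10(records[row.parent_id].coverage + 1.0)
    sd = logcov.std()
    z = (logcov - logcov.mean()) / sd if sd > 0 else np.zeros(n)
    X = np.column_stack([profiles, z])
    n_comp = min(config.pca_variance, 1.0) if n > X.shape[1] else min(n - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=config.seed)
    Y = pca.fit_transform(X)
    bics = {}
    best_k, best_gmm, best_bic = 1, None, np.inf
    for k in range(1, min(config.max_bins, n) + 1):
        gmm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            random_state=config.seed,
            n_init=2,
            reg_covar=1e-6,
        )
        gmm.fit(Y)
        bic = gmm.bic(Y)
        bics[k] = float(bic)
        if bic < best_bic - 1e-9:
            best_bic, best_k, best_gmm = bic, k, gmm
    frag_labels = pd.Series(best_gmm.predict(Y), index=frags["fragment_id"])
    lengths = (frags["end"] - frags["start"]).to_numpy()
    vote: dict[str, dict[int, int]] = {}
    for row, lab, ln in zip(frags.itertuples(index=False), frag_labels.to_numpy(), lengths):
        vote.setdefault(row.parent_id, {}).setdefault(int(lab), 0)
        vote[row.parent_id][int(lab)] += int(ln)
    contig_labels = {
        cid: min(d, key=lambda b: (-d[b], b)) for cid, d in vote.items()
    }
    report = {"k": best_k, "bic": bics, "pca_components": int(Y.shape[1])}
    return frag_labels, contig_labels, report


def _make_bins(
    records: dict[str, ContigRecord],
    contig_labels: dict[str, int],
    taxon_calls: dict[str, str],
) -> dict[int, Bin]:
    groups: dict[int, list[str]] = {}
    for cid, lab in contig_labels.items():
        groups.setdefault(lab, []).append(cid)
    bins: dict[int, Bin] = {}
    for lab, members in groups.items():
        members = sorted(members)
        recs = [records[c] for c in members]
        total = sum(r.length for r in recs)
        tax_bp: dict[str, float] = {}
        for r in recs:
            call = taxon_calls.get(r.contig_id, NO_HIT)
            tax_bp[call] = tax_bp.get(call, 0.0) + r.length
        bins[lab] = Bin(
            bin_id=lab,
            members=members,
            total_bp=total,
            median_gc=float(np.median([r.gc for r in recs])),
            median_coverage=float(np.median([r.coverage for r in recs])),
            taxon_bp_fraction={k: v / total for k, v in tax_bp.items()},
        )
    return bins


def select_anchor_bin(
    bins: dict[int, Bin],
    taxon_calls: dict[str, str],
    records: dict[str, ContigRecord],
    config: TaxonomyConfig | None = None,
) -> int:
    """Bin with the most target-taxon bases; ties to larger bin, then lower id."""
    config = config or TaxonomyConfig()
    if not bins:
        raise ValueError("no bins")
    best = None
    for b in bins.values():
        target_bp = sum(
            records[c].length
            for c in b.members
            if taxon_calls.get(c, NO_HIT) == config.target_taxon
        )
        key = (-target_bp, -b.total_bp, b.bin_id)
        if best is None or key < best[0]:
            best = (key, b.bin_id, target_bp)
    if best[2] == 0:
        raise ValueError("no anchor evidence: no contig labelled with the target taxon")
    return best[1]


def merge_tail_bins(
    bins: dict[int, Bin],
    anchor: int,
    config: BinningConfig | None = None,
    taxonomy: TaxonomyConfig | None = None,
) -> tuple[set[str], list[dict]]:
    """Merge low-GC, coverage-consistent, low-contaminant bins into the anchor.

    A non-anchor bin merges iff (i) its median coverage is within
    ``coverage_ratio_tol``-fold of the anchor's, (ii) its median GC does not
    exceed the anchor's by more than ``gc_slack``, and (iii) at most
    ``contaminant_bp_frac`` of its bases are labelled with a taxon other than
    the target or NO_HIT. Bins are evaluated independently (no chaining).
    """
    config = config or BinningConfig()
    taxonomy = taxonomy or TaxonomyConfig()
    a = bins[anchor]
    merged = set(a.members)
    decisions = []
    for b in sorted(bins.values(), key=lambda x: x.bin_id):
        if b.bin_id == anchor:
            continue
        cov_ratio = abs(np.log2(b.median_coverage / a.median_coverage))
        gc_excess = b.median_gc - a.median_gc
        foreign = sum(
            frac
            for taxon, frac in b.taxon_bp_fraction.items()
            if taxon not in (taxonomy.target_taxon, NO_HIT)
        )
        ok_cov = cov_ratio <= np.log2(config.coverage_ratio_tol) + 1e-12
        ok_gc = gc_excess <= config.gc_slack + 1e-12
        ok_tax = foreign <= config.contaminant_bp_frac + 1e-12
        take = ok_cov and ok_gc and ok_tax
        decisions.append(
            {
                "bin_id": b.bin_id,
                "merged": bool(take),
                "log2_coverage_ratio": float(cov_ratio),
                "gc_excess": float(gc_excess),
                "foreign_bp_fraction": float(foreign),
            }
        )
        if take:
            merged |= set(b.members)
    return merged, decisions


def filter_contaminants(
    merged: set[str],
    taxon_calls: dict[str, str],
    config: TaxonomyConfig | None = None,
) -> set[str]:
    """Keep contigs called as the target taxon or with no hit at all."""
    config = config or TaxonomyConfig()
    if not merged:
        raise ValueError("empty contig set")
    kept = {
        c
        for c in merged
        if taxon_calls.get(c, NO_HIT) in (config.target_taxon, NO_HIT)
    }
    if not kept:
        raise ValueError("mycobiont set empty after filtering")
    return kept


def run_binning(
    contigs: dict[str, str],
    coverage: pd.DataFrame,
    hits: pd.DataFrame,
    config: BinningConfig | None = None,
    taxonomy: TaxonomyConfig | None = None,
) -> tuple[set[str], dict]:
    """Full mycobiont isolation pipeline; returns (contig ids, stage report)."""
    config = config or BinningConfig()
    taxonomy = taxonomy or TaxonomyConfig()
    records = compute_contig_features(contigs, coverage)
    calls = assign_taxonomy(hits, taxonomy)
    fragments = fragment_contigs(contigs, config.fragment_size)
    _, contig_labels, model_report = cluster_fragments(
        contigs, records, fragments, config
    )
    bins = _make_bins(records, contig_labels, calls)
    anchor = select_anchor_bin(bins, calls, records, taxonomy)
    merged, merge_decisions = merge_tail_bins(bins, anchor, config, taxonomy)
    final = filter_contaminants(merged, calls, taxonomy)
    removed = sorted(merged - final)
    report = {
        "n_contigs": len(contigs),
        "n_fragments": len(fragments),
        "model": model_report,
        "bins": {
            int(b.bin_id): {
                "n_contigs": len(b.members),
                "total_bp": b.total_bp,
                "median_gc": b.median_gc,
                "median_coverage": b.median_coverage,
                "taxon_bp_fraction": b.taxon_bp_fraction,
            }
            for b in bins.values()
        },
        "anchor_bin": int(anchor),
        "merge_decisions": merge_decisions,
        "n_removed_contaminants": len(removed),
        "removed_contigs": removed,
        "n_final": len(final),
        "thresholds": {
            "coverage_ratio_tol": config.coverage_ratio_tol,
            "gc_slack": config.gc_slack,
            "contaminant_bp_frac": config.contaminant_bp_frac,
            "note": "tail-merge thresholds are pipeline defaults, configurable",
        },
    }
    return final, report
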