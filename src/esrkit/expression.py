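"""Downstream analysis of per-gene fold-change / FDR tables.

The upstream differential-expression engine (read alignment, counting, GLM
fits) is consumed, never computed: inputs are long tables of log2 fold-change
per (gene, strain, timepoint) and an FDR per gene x timepoint for each
mutant-vs-wild-type contrast. This module reproduces the downstream steps:

* responsive-gene selection (significant at >= 2 timepoints, FDR < 0.05);
* induction/repression defect calls in mutants;
* k-means partitioning (k = 10) on concatenated per-strain fold-changes plus
  mutant-minus-wild-type differences;
* promoter motif scanning (STRE pentamer CCCCT, PAC-type GATGAG) over both
  strands with non-overlapping hit counting;
* hypergeometric enrichment of transcription-factor target sets per cluster
  with Benjamini-Hochberg correction, and the distribution of per-gene
  regulator counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .phenotypes import WILCOXON_RANK_SUM, compare_groups

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGTN]",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

MAX_PROMOTER_LEN = 500


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionTable:
    """Long fold-change table with columns gene, strain, timepoint, log2fc,
    fdr. The ``fdr`` column is the per-timepoint mutant-vs-WT contrast FDR
    (NaN where no contrast applies, e.g. the wild-type rows)."""

    data: pd.DataFrame

    REQUIRED = ("gene", "strain", "timepoint", "log2fc", "fdr")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ExpressionError(f"missing columns: {missing}")
        dup = self.data.duplicated(["gene", "strain", "timepoint"])
        if dup.any():
            raise ExpressionError("duplicate (gene, strain, timepoint) rows")

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    @property
    def timepoints(self) -> list:
        return sorted(self.data["timepoint"].unique())

    def strain_matrix(self, strain: str, value: str = "log2fc") -> pd.DataFrame:
        sub = self.data[self.data["strain"] == strain]
        if sub.empty:
            raise ExpressionError(f"no rows for strain {strain!r}")
        return sub.pivot(index="gene", columns="timepoint", values=value).sort_index()


@dataclass
class GeneSetCollection:
    """Named gene sets (TF targets, cluster memberships) over a universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        for name, s in self.sets.items():
            extra = s - self.universe
            if extra:
                raise ExpressionError(
                    f"set {name!r} has {len(extra)} genes outside the universe"
                )


@dataclass(frozen=True)
class PromoterSeq:
    """Upstream regulatory sequence, at most 500 bases immediately 5' of the
    start codon."""

    gene: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) > MAX_PROMOTER_LEN:
            raise ExpressionError(
                f"promoter of {self.gene} exceeds {MAX_PROMOTER_LEN} bp"
            )
        if re.search("[^ACGTN]", seq):
            raise ExpressionError(f"promoter of {self.gene} has non-ACGTN characters")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    cluster_size: int
    universe_size: int
    p: float
    fdr: float


def select_responsive(
    table: ExpressionTable,
    contrast: str,
    alpha: float = 0.05,
    min_timepoints: int = 2,
) -> list[str]:
    """Genes whose mutant-vs-WT contrast is significant (fdr < alpha) at at
    least ``min_timepoints`` timepoints."""
    fdr = table.strain_matrix(contrast, "fdr")
    if fdr.shape[1] < min_timepoints:
        raise ExpressionError(
            f"contrast {contrast!r} has {fdr.shape[1]} timepoints, "
            f"needs >= {min_timepoints}"
        )
    n_sig = (fdr < alpha).sum(axis=1)
    return sorted(fdr.index[n_sig >= min_timepoints])


INDUCTION_DEFECT = "induction_defect"
REPRESSION_DEFECT = "repression_defect"
NO_DEFECT = "none"


def call_defect(wt_fc, mut_fc) -> str:
    """Call a mutant induction or repression defect for one gene.

    The wild-type direction is the sign holding in a strict majority of
    timepoints; a defect is called when the mutant's |log2 fold-change| is
    smaller than the wild-type's in a strict majority of the timepoints with
    that direction.
    """
    wt = np.asarray(wt_fc, dtype=float)
    mut = np.asarray(mut_fc, dtype=float)
    if wt.shape != mut.shape:
        raise ExpressionError("wild-type and mutant vectors must align")
    if wt.size < 3:
        raise ExpressionError("need >= 3 timepoints to call a defect")
    n = wt.size
    n_pos, n_neg = int((wt > 0).sum()), int((wt < 0).sum())
    if n_pos > n / 2:
        direction = 1
    elif n_neg > n / 2:
        direction = -1
    else:
        return NO_DEFECT
    mask = np.sign(wt) == direction
    smaller = np.abs(mut[mask]) < np.abs(wt[mask])
    if smaller.sum() > mask.sum() / 2:
        return INDUCTION_DEFECT if direction > 0 else REPRESSION_DEFECT
    return NO_DEFECT


def defect_calls(table: ExpressionTable, wt_strain: str, mut_strain: str) -> pd.Series:
    wt = table.strain_matrix(wt_strain)
    mut = table.strain_matrix(mut_strain)
    common = wt.index.intersection(mut.index)
    return pd.Series(
        {g: call_defect(wt.loc[g].to_numpy(), mut.loc[g].to_numpy()) for g in common},
        name="defect",
    )


def build_feature_matrix(
    table: ExpressionTable, wt_strain: str, mutant_strains: list[str], genes=None
) -> pd.DataFrame:
    """Concatenate per-strain fold-change time courses with mutant-minus-WT
    differences at each timepoint, unscaled — the k-means feature space."""
    wt = table.strain_matrix(wt_strain)
    blocks = [wt.add_prefix(f"{wt_strain}_t")]
    for m in mutant_strains:
        fm = table.strain_matrix(m).reindex(wt.index)
        blocks.append(fm.add_prefix(f"{m}_t"))
        blocks.append((fm - wt).add_prefix(f"{m}_minus_{wt_strain}_t"))
    X = pd.concat(blocks, axis=1)
    if genes is not None:
        X = X.loc[[g for g in genes if g in X.index]]
    return X


def kmeans_partition(
    features: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    *,
    n_init: int = 50,
    missing: str = "drop",
) -> pd.Series:
    """Partition genes into k clusters by k-means (k-means++ init, ``n_init``
    restarts, fixed seed). ``missing`` is ``"drop"`` (default) or ``"impute"``
    (column mean)."""
    X = features.copy()
    if X.isna().any().any():
        if missing == "drop":
            X = X.dropna()
        elif missing == "impute":
            X = X.fillna(X.mean())
        else:
            raise ExpressionError(f"unknown missing-value policy {missing!r}")
    if k > X.drop_duplicates().shape[0]:
        raise ExpressionError(f"k={k} exceeds {X.drop_duplicates().shape[0]} distinct rows")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(X.to_numpy(dtype=float))
    return pd.Series(labels, index=X.index, name="cluster")


# ---------------------------------------------------------------------------
# motif scanning

def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _iupac_regex(motif: str) -> re.Pattern:
    motif = motif.upper()
    bad = set(motif) - set(IUPAC)
    if bad:
        raise ExpressionError(f"invalid IUPAC characters in motif: {sorted(bad)}")
    # lookahead makes overlapping candidate matches visible to the scanner
    return re.compile("(?=(" + "".join(IUPAC[c] for c in motif) + "))")


def find_motif_sites(sequence: str, motif: str) -> list[tuple[int, str]]:
    """All candidate match start positions (0-based, promoter coordinates) on
    both strands, overlaps included. A reverse-strand hit is reported at the
    position its interval occupies on the forward sequence."""
    seq = sequence.upper()
    if len(motif) > len(seq):
        raise ExpressionError("motif longer than sequence")
    if re.search("[^ACGTN]", seq):
        raise ExpressionError("sequence has non-ACGTN characters")
    fwd = _iupac_regex(motif)
    rev = _iupac_regex(reverse_complement(motif))
    sites = [(m.start(), "+") for m in fwd.finditer(seq)]
    sites += [(m.start(), "-") for m in rev.finditer(seq)]
    # leftmost first; forward strand wins ties
    return sorted(sites, key=lambda s: (s[0], s[1]))


def scan_motif(promoter: PromoterSeq | str, motif: str) -> dict:
    """Count non-overlapping motif occurrences over both strands.

    All candidate intervals (either strand) are collected, then accepted
    greedily left to right, skipping any interval overlapping an accepted one
    — a reverse hit on the same interval as an accepted forward hit is
    suppressed. Greedy-by-left-endpoint is optimal on interval paths, so the
    count equals the maximum independent set of match intervals. Positions in
    the returned hit list are 1-based.
    """
    seq = promoter.sequence if isinstance(promoter, PromoterSeq) else promoter
    w = len(motif)
    accepted: list[tuple[int, str]] = []
    last_end = -1  # exclusive end of last accepted interval
    for start, strand in find_motif_sites(seq, motif):
        if start >= last_end:
            accepted.append((start + 1, strand))
            last_end = start + w
    return {"count": len(accepted), "hits": accepted, "motif": motif.upper()}


def motif_counts(promoters: list[PromoterSeq], motifs: list[str]) -> pd.DataFrame:
    rows = []
    for p in promoters:
        row = {"gene": p.gene}
        for m in motifs:
            row[m.upper()] = scan_motif(p, m)["count"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# enrichment

def enrich(
    cluster: set[str],
    collection: GeneSetCollection,
    *,
    alternative: str = "greater",
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of each named set in a gene cluster.

    ``alternative="greater"`` tests over-representation (upper tail,
    P(X >= overlap)); ``"less"`` tests under-representation (lower tail,
    P(X <= overlap)), used e.g. for clusters depleted of upstream STRE
    motifs. BH correction is applied across all sets tested for the cluster.
    """
    if not collection.universe:
        raise ExpressionError("empty universe")
    cluster = set(cluster)
    extra = cluster - collection.universe
    if extra:
        raise ExpressionError(f"{len(extra)} cluster genes outside the universe")
    M, N = len(collection.universe), len(cluster)
    names, pvals, meta = [], [], []
    for name, s in sorted(collection.sets.items()):
        n = len(s)
        k = len(cluster & s)
        if alternative == "greater":
            p = float(stats.hypergeom.sf(k - 1, M, n, N))
        elif alternative == "less":
            p = float(stats.hypergeom.cdf(k, M, n, N))
        else:
            raise ExpressionError(f"unknown alternative {alternative!r}")
        names.append(name)
        pvals.append(min(p, 1.0))
        meta.append((k, n))
    fdrs = bh_adjust(pvals)
    return [
        EnrichmentResult(
            set_name=names[i],
            overlap=meta[i][0],
            set_size=meta[i][1],
            cluster_size=N,
            universe_size=M,
            p=pvals[i],
            fdr=fdrs[i],
        )
        for i in range(len(names))
    ]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def regulator_counts(
    genes, tf_targets: GeneSetCollection, *, pseudocount: int = 1
) -> pd.Series:
    """Per-gene log2(regulator count + 1): the number of TF target sets
    containing the gene, with a +1 pseudocount so unregulated genes map to 0."""
    counts = {
        g: sum(g in s for s in tf_targets.sets.values()) for g in genes
    }
    return pd.Series(
        {g: np.log2(c + pseudocount) for g, c in counts.items()}, name="log2_regulators"
    )


def regulator_count_stats(
    clusters: dict[str, set[str]],
    tf_targets: GeneSetCollection,
    background: set[str],
) -> pd.DataFrame:
    """Compare each cluster's log2 regulator-count distribution to the
    background by rank-sum test, BH-corrected across clusters."""
    bg = regulator_counts(sorted(background), tf_targets)
    rows = []
    for name, genes in sorted(clusters.items()):
        if not genes:
            import warnings

            warnings.warn(f"cluster {name!r} is empty; skipped", stacklevel=2)
            continue
        vals = regulator_counts(sorted(genes), tf_targets)
        _, p = compare_groups(vals.to_numpy(), bg.to_numpy(), mode=WILCOXON_RANK_SUM)
        rows.append(
            {
                "cluster": name,
                "n_genes": len(genes),
                "median_log2_regulators": float(vals.median()),
                "background_median": float(bg.median()),
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["fdr"] = bh_adjust(df["p"].to_numpy())
    return df
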