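"""Population analysis of a TIP genotype matrix.

Covers MAF filtering, allele-sharing distances and neighbor-joining trees,
variance-standardized PCA of presence/absence dosages, a Fisher's-exact
enrichment scan between two accession groups (with -log10 and z-score
normalization of the p-values), and the paired comparison of per-gene core
TIP versus core nonsynonymous SNP p-values.

Genotype codes: CC = homozygous TE presence, GG = absence, CG = heterozygous,
NN = missing.  Throughout, CG counts as a carrier in enrichment scans,
contributes dosage 1 to PCA, and 0.5 to distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

CODES = ("CC", "GG", "CG", "NN")

_DOSAGE = {"GG": 0.0, "CG": 1.0, "CC": 2.0, "NN": np.nan}


def _dosage_matrix(codes: pd.DataFrame) -> np.ndarray:
    """loci x accessions dosage of the presence allele (NN -> NaN)."""
    arr = codes.to_numpy(dtype="U2")
    out = np.full(arr.shape, np.nan)
    for code, dose in _DOSAGE.items():
        out[arr == code] = dose
    return out


def minor_allele_frequency(codes: pd.DataFrame) -> pd.Series:
    """Per-locus MAF of the presence/absence allele.

    CG contributes one allele of each kind; NN calls are excluded from the
    denominator (2 x non-NN count).
    """
    d = _dosage_matrix(codes)
    called = np.sum(~np.isnan(d), axis=1)
    with np.errstate(invalid="ignore"):
        p = np.nansum(d, axis=1) / (2.0 * called)
    maf = np.minimum(p, 1.0 - p)
    return pd.Series(maf, index=codes.index, name="maf")


def maf_filter(codes: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Remove loci with MAF <= threshold (the removal list is logged)."""
    maf = minor_allele_frequency(codes)
    drop = codes.index[(maf <= threshold) | maf.isna()]
    if len(drop):
        warnings.warn(f"maf_filter: removed {len(drop)} loci with MAF <= {threshold}")
    return codes.drop(index=drop)


def pairwise_distance(codes: pd.DataFrame) -> pd.DataFrame:
    """Allele-sharing mismatch fraction between accession pairs.

    Over loci where both accessions are non-NN: CC vs GG scores 1, either
    homozygote vs CG scores 0.5, identical codes 0.  Errors on all-NN
    accessions and on pairs sharing no called locus.
    """
    if codes.shape[1] < 2:
        raise ValueError("need at least 2 accessions")
    d = _dosage_matrix(codes) / 2.0  # CC=1, CG=0.5, GG=0
    called = ~np.isnan(d)
    empty = np.flatnonzero(~called.any(axis=0))
    if empty.size:
        raise ValueError(f"all-NN accession(s): {', '.join(codes.columns[empty])}")
    n = codes.shape[1]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[:, i] & called[:, j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"accessions {codes.columns[i]} and {codes.columns[j]} share no called loci"
                )
            out[i, j] = out[j, i] = float(np.abs(d[both, i] - d[both, j]).mean())
    return pd.DataFrame(out, index=codes.columns, columns=codes.columns)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dist: pd.DataFrame) -> str:
    """Saitou-Nei neighbor joining; returns a newick string with lengths.

    Ties in the Q criterion break on the smallest (i, j) index pair; negative
    branch lengths are clamped to zero with the deficit transferred to the
    sister edge, preserving the path length between the joined leaves.
    """
    D = np.asarray(dist, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    labels = [str(x) for x in dist.index]
    nodes = list(labels)
    D = D.copy()
    while len(nodes) > 2:
        m = len(nodes)
        row_sums = D.sum(axis=1)
        Q = (m - 2) * D - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest Q; ties -> smallest (i, j)
        i, j = min(
            ((a, b) for a in range(m) for b in range(a + 1, m)),
            key=lambda ab: (Q[ab[0], ab[1]], ab[0], ab[1]),
        )
        li = 0.5 * D[i, j] + (row_sums[i] - row_sums[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        du = 0.5 * (D[:, i] + D[:, j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = du[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
    return f"({nodes[0]}:{D[0, 1]:.10g},{nodes[1]});"


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    coordinates: pd.DataFrame        # accessions x PCs (unit-norm eigenvectors)
    explained_variance: np.ndarray   # eigenvalues
    explained_ratio: np.ndarray


def pca(codes: pd.DataFrame, k: int = 20) -> PCAResult:
    """Variance-standardized genotype PCA (plink convention).

    Dosages GG=0, CG=1, CC=2 are mean-centered per locus and scaled by
    sqrt(2p(1-p)) with p the presence-allele frequency; NN is imputed to the
    locus mean.  Coordinates are the top-k eigenvectors of the accession x
    accession covariance; each PC's largest-magnitude loading is made
    positive.
    """
    X = _dosage_matrix(codes)
    n_loci, n_acc = X.shape
    if k >= n_acc:
        warnings.warn(f"k={k} >= {n_acc} accessions; truncating to {n_acc - 1}")
        k = n_acc - 1
    mean = np.nanmean(X, axis=1)
    p = mean / 2.0
    X = np.where(np.isnan(X), mean[:, None], X) - mean[:, None]
    scale = np.sqrt(2.0 * p * (1.0 - p))
    ok = scale > 0
    X[ok] /= scale[ok, None]
    X[~ok] = 0.0
    cov = (X.T @ X) / max(n_loci, 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.maximum(vals[order], 0.0), vecs[:, order]
    vecs = vecs[:, :k].copy()
    for c in range(vecs.shape[1]):
        if vecs[np.argmax(np.abs(vecs[:, c])), c] < 0:
            vecs[:, c] = -vecs[:, c]
    total = vals.sum()
    ratio = vals[:k] / total if total > 0 else np.zeros(k)
    coords = pd.DataFrame(
        vecs, index=codes.columns, columns=[f"PC{i + 1}" for i in range(vecs.shape[1])]
    )
    return PCAResult(coords, vals[:k], ratio)


# ---------------------------------------------------------------------------
# Fisher's exact scan


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    Two-sided means the sum of hypergeometric probabilities of all tables
    with the observed margins whose point probability does not exceed the
    observed one.  A zero margin returns p = 1 with a warning.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be non-negative integers")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        warnings.warn("fisher_exact_2x2: zero margin, p = 1 by convention")
        return 1.0
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)


@dataclass
class SelectionResult:
    locus_id: str
    a: int  # derived carriers
    b: int  # derived non-carriers
    c: int  # control carriers
    d: int  # control non-carriers
    p: float
    neg_log10_p: float
    z: float = float("nan")


def enrichment_scan(
    codes: pd.DataFrame,
    derived: list[str],
    control: list[str],
) -> pd.DataFrame:
    """Per-locus Fisher's exact contrast of carrier frequency between groups.

    Carriers are CC or CG accessions, non-carriers GG; NN is excluded.  The
    per-locus p-values are normalized by -log10 and then z-scored across all
    scanned loci.  Also emits Bonferroni and Benjamini-Hochberg columns for
    convenience (rankings use the raw p).
    """
    derived, control = list(derived), list(control)
    if not derived or not control:
        raise ValueError("both groups must be non-empty")
    if set(derived) & set(control):
        raise ValueError("derived and control groups overlap")
    rows = []
    for lid in codes.index:
        row = codes.loc[lid]
        counts = []
        for grp in (derived, control):
            sub = row[grp]
            carriers = int(((sub == "CC") | (sub == "CG")).sum())
            noncar = int((sub == "GG").sum())
            counts.extend([carriers, noncar])
        a, b, c, d = counts
        if a + b == 0 or c + d == 0:
            warnings.warn(f"locus {lid}: a group is entirely NN; skipped")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = fisher_exact_2x2(a, b, c, d)
        rows.append(SelectionResult(lid, a, b, c, d, p, -np.log10(p)))
    if not rows:
        return pd.DataFrame(
            columns=["locus_id", "a", "b", "c", "d", "p", "neg_log10_p", "z", "bonferroni", "bh"]
        )
    nl = np.array([r.neg_log10_p for r in rows])
    sd = nl.std()
    z = (nl - nl.mean()) / sd if sd > 0 else np.zeros_like(nl)
    pvals = np.array([r.p for r in rows])
    m = len(pvals)
    bonf = np.minimum(pvals * m, 1.0)
    order = np.argsort(pvals)
    bh = np.empty(m)
    ranked = pvals[order] * m / (np.arange(m) + 1)
    bh[order] = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
    df = pd.DataFrame(
        {
            "locus_id": [r.locus_id for r in rows],
            "a": [r.a for r in rows],
            "b": [r.b for r in rows],
            "c": [r.c for r in rows],
            "d": [r.d for r in rows],
            "p": pvals,
            "neg_log10_p": nl,
            "z": z,
            "bonferroni": bonf,
            "bh": bh,
        }
    )
    return df.sort_values("p", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# core TIP vs core nonsynonymous SNP


@dataclass
class CoreVariantRecord:
    gene_id: str
    core_tip_p: float
    core_snp_p: float | None


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    mean_tip: float
    mean_snp: float
    n_pairs: int
    degenerate: bool = False


def core_variant_comparison(
    tip_p: dict[str, list[float]],
    snp_p: dict[str, list[float]],
    log10: bool = False,
) -> tuple[PairedTestResult, list[CoreVariantRecord]]:
    """Paired t-test of per-gene core TIP p versus core nonsynonymous SNP p.

    The core variant of a gene is its smallest p-value in each class.  Only
    genes with at least one p in both classes enter the paired test; genes
    lacking SNPs are reported with core_snp_p = None.  With ``log10`` the
    test runs on -log10-transformed p-values.
    """
    records = []
    x, y = [], []
    for gene, tips in tip_p.items():
        if not tips:
            continue
        ctp = min(tips)
        snps = snp_p.get(gene) or []
        csp = min(snps) if snps else None
        records.append(CoreVariantRecord(gene, ctp, csp))
        if csp is not None:
            x.append(ctp)
            y.append(csp)
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 genes with both variant classes, got {n}")
    xa, ya = np.asarray(x), np.asarray(y)
    if log10:
        xa, ya = -np.log10(xa), -np.log10(ya)
    diffs = xa - ya
    if np.allclose(diffs.std(ddof=1), 0.0):
        # zero-variance differences: t undefined; report the degenerate case
        t = 0.0 if np.allclose(diffs, 0) else np.inf * np.sign(diffs.mean())
        p = 1.0 if np.allclose(diffs, 0) else 0.0
        res = PairedTestResult(float(t), n - 1, p, float(xa.mean()), float(ya.mean()), n, True)
        return res, records
    t, p = sps.ttest_rel(xa, ya)
    return PairedTestResult(float(t), n - 1, float(p), float(xa.mean()), float(ya.mean()), n), records


def cds_length_contrast(
    shorter_subset: int, longer_subset: int, shorter_all: int, longer_all: int
) -> float:
    """Fisher's exact contrast of shorter/longer CDS counts in a gene subset
    against all syntenic gene pairs."""
    return fisher_exact_2x2(shorter_subset, longer_subset, shorter_all, longer_all)
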