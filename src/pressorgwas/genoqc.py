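"""Genotype I/O and quality control.

Holds additive dosages (expected effect-allele counts in [0, 2], fractional
for imputed genotypes) in a samples x variants matrix, and implements the
standard pre-association screens: imputation info score, variant and sample
call rates, minor allele frequency, Hardy-Weinberg equilibrium, IBD-based
relatedness pruning, and principal components for population structure.

Threshold defaults: info > 0.7, sample call rate >= 0.95, variant call rate
>= 0.99, MAF >= 0.01, HWE P >= 1e-7 — the usual post-imputation GWAS recipe.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "QCReport",
    "read_vcf",
    "write_vcf",
    "variant_filter",
    "sample_filter",
    "hwe_test",
    "hard_call",
    "estimate_relatedness",
    "prune_related",
    "compute_pcs",
]

#: pi_hat cutoff between second-degree (0.25) and third-degree (0.125)
#: relatives: pairs at or above it are treated as first/second degree.
RELATEDNESS_THRESHOLD = 0.1875

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "info_score"]


@dataclass
class GenotypeMatrix:
    """Samples x variants additive dosage matrix with metadata.

    dosages: float array, np.nan for missing; effect allele is the VCF alt.
    variants: DataFrame with chrom, pos (1-based), id, ref, alt, info_score.
    samples: DataFrame with id and optionally phase ("I" / "II") and PC1..PCk.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n, m = self.dosages.shape
        if len(self.samples) != n or len(self.variants) != m:
            raise ValueError(
                f"shape mismatch: dosages {n}x{m}, {len(self.samples)} samples, "
                f"{len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0) < -1e-9 or np.nanmax(
                self.dosages, initial=0
            ) > 2 + 1e-9:
                raise ValueError("dosages must lie in [0, 2]")
        for df, what in ((self.variants, "variant"), (self.samples, "sample")):
            if df["id"].duplicated().any():
                raise ValueError(f"duplicate {what} ids")
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Effect (alt) allele frequency per variant, from non-missing dosages."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1 - p)

    def variant_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(si, vi)].copy(),
            variants=self.variants.iloc[vi].reset_index(drop=True),
            samples=self.samples.iloc[si].reset_index(drop=True),
        )

    def column(self, variant_id: str) -> np.ndarray:
        j = self.variants.index[self.variants["id"] == variant_id]
        if len(j) != 1:
            raise KeyError(variant_id)
        return self.dosages[:, j[0]]


@dataclass
class QCReport:
    """Per-filter removal bookkeeping for one QC pass."""

    n_input: int
    removed: dict[str, list[str]] = field(default_factory=dict)
    hwe_p: pd.Series | None = None
    pi_hat: pd.DataFrame | None = None

    @property
    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.removed.items()}

    @property
    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed.values())


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a plain-text VCF 4.2 with both GT (hard call) and DS fields."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=INFO_SCORE,Number=1,Type=Float,Description="Imputation info score">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n')
        for chrom in pd.unique(gm.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples["id"].astype(str))
            + "\n"
        )
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, var in gm.variants.iterrows():
            ds = gm.dosages[:, j]
            cells = []
            for d in ds:
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    cells.append(f"{gt_strings[int(_hard_call_scalar(d))]}:{d:.6g}")
            info = f"INFO_SCORE={var['info_score']:.6g}"
            fh.write(
                f"{var['chrom']}\t{int(var['pos'])}\t{var['id']}\t{var['ref']}\t"
                f"{var['alt']}\t.\tPASS\t{info}\tGT:DS\t" + "\t".join(cells) + "\n"
            )


def _hard_call_scalar(d: float) -> float:
    if d < 0.5:
        return 0
    if d < 1.5:
        return 1
    return 2


def hard_call(dosages: np.ndarray) -> np.ndarray:
    """Round dosages to {0,1,2} at thresholds (0.5, 1.5); NaN passes through."""
    out = np.where(dosages < 0.5, 0.0, np.where(dosages < 1.5, 1.0, 2.0))
    return np.where(np.isnan(dosages), np.nan, out)


def read_vcf(path, phase: str | None = None) -> tuple[GenotypeMatrix, int]:
    """Read a VCF 4.2 into a GenotypeMatrix.

    DS is preferred when present, otherwise GT is converted to {0,1,2}.
    Multiallelic records are skipped; the second return value is their count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    cols, var_rows = [], []
    n_multiallelic = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multiallelic += 1
            continue
        ds = None
        try:
            arr = variant.format("DS")
        except KeyError:
            arr = None
        if arr is not None:
            ds = np.asarray(arr, dtype=float).reshape(-1)
            ds[ds < -0.5] = np.nan  # cyvcf2 encodes missing floats as large negatives
        else:
            gt = np.asarray(variant.gt_types, dtype=float)
            # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            ds = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        cols.append(ds)
        info = variant.INFO.get("INFO_SCORE")
        var_rows.append(
            {
                "chrom": variant.CHROM,
                "pos": variant.POS,
                "id": variant.ID or f"{variant.CHROM}:{variant.POS}",
                "ref": variant.REF,
                "alt": variant.ALT[0],
                "info_score": float(info) if info is not None else 1.0,
            }
        )
    vcf.close()
    dosages = (
        np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    )
    samples = pd.DataFrame({"id": sample_ids})
    if phase is not None:
        samples["phase"] = phase
    return (
        GenotypeMatrix(dosages=dosages, variants=pd.DataFrame(var_rows, columns=VARIANT_COLUMNS), samples=samples),
        n_multiallelic,
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df Pearson chi-square test of Hardy-Weinberg proportions.

    Expected genotype counts are n*(p^2, 2pq, q^2) with p estimated from the
    observed allele counts. Monomorphic input returns P = 1 by convention.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotypes")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1 - p
    if p <= 0 or q <= 0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_pvalues(gm: GenotypeMatrix) -> np.ndarray:
    calls = hard_call(gm.dosages)
    out = np.empty(gm.n_variants)
    for j in range(gm.n_variants):
        c = calls[:, j]
        c = c[~np.isnan(c)]
        out[j] = hwe_test(int((c == 2).sum()), int((c == 1).sum()), int((c == 0).sum()))
    return out


# ---------------------------------------------------------------------------
# Variant / sample filters
# ---------------------------------------------------------------------------


def variant_filter(
    gm: GenotypeMatrix,
    min_info: float = 0.7,
    min_call_rate: float = 0.99,
    min_maf: float = 0.01,
    min_hwe_p: float = 1e-7,
) -> tuple[GenotypeMatrix, QCReport]:
    """Variant QC in the fixed order info -> call rate -> MAF -> HWE.

    Each variant is removed by the *first* filter it fails, so the per-filter
    counts in the report are disjoint and sum to the total removed.
    """
    report = QCReport(n_input=gm.n_variants)
    ids = gm.variants["id"]
    alive = np.ones(gm.n_variants, dtype=bool)

    fail = alive & ~(gm.variants["info_score"].to_numpy() > min_info)
    report.removed["info"] = list(ids[fail])
    alive &= ~fail

    fail = alive & (gm.variant_call_rate() < min_call_rate)
    report.removed["call_rate"] = list(ids[fail])
    alive &= ~fail

    fail = alive & (gm.maf() < min_maf)
    report.removed["maf"] = list(ids[fail])
    alive &= ~fail

    hwe_p = _hwe_pvalues(gm)
    report.hwe_p = pd.Series(hwe_p, index=ids, name="hwe_p")
    fail = alive & (hwe_p < min_hwe_p)
    report.removed["hwe"] = list(ids[fail])
    alive &= ~fail

    return gm.subset(variant_idx=np.flatnonzero(alive)), report


def sample_filter(
    gm: GenotypeMatrix, min_call_rate: float = 0.95
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove samples whose genotyping call rate is below ``min_call_rate``."""
    report = QCReport(n_input=gm.n_samples)
    ok = gm.sample_call_rate() >= min_call_rate
    report.removed["call_rate"] = list(gm.samples["id"][~ok])
    return gm.subset(sample_idx=np.flatnonzero(ok)), report


# ---------------------------------------------------------------------------
# Relatedness (method-of-moments IBD)
# ---------------------------------------------------------------------------


def estimate_relatedness(gm: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise pi_hat by the method-of-moments IBS decomposition.

    For each sample pair the observed counts of loci sharing 0/1/2 alleles
    identical by state are decomposed into IBD 0/1/2 proportions using their
    allele-frequency expectations (the classic PLINK --genome estimator,
    without the finite-sample correction), and
    ``pi_hat = P(IBD=1)/2 + P(IBD=2)``. Dosages are hard-called first.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if gm.n_variants < 50:
        warnings.warn(
            f"only {gm.n_variants} variants: pi_hat estimates will be noisy",
            stacklevel=2,
        )
    g = hard_call(gm.dosages)
    valid = ~np.isnan(g)
    gz = np.nan_to_num(g)
    ind = {v: ((gz == v) & valid).astype(float) for v in (0.0, 1.0, 2.0)}

    ibs0 = ind[0.0] @ ind[2.0].T + ind[2.0] @ ind[0.0].T
    ibs2 = sum(ind[v] @ ind[v].T for v in (0.0, 1.0, 2.0))
    m_pair = valid.astype(float) @ valid.astype(float).T
    ibs1 = m_pair - ibs0 - ibs2

    p = np.nanmean(g, axis=0) / 2.0
    q = 1 - p
    poly = (p > 0) & (p < 1)
    p, q = p[poly], q[poly]
    m_poly = poly.sum()
    e0_ibd0 = float(np.sum(2 * p**2 * q**2))
    e1_ibd0 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e2_ibd0 = float(np.sum(p**4 + q**4 + 4 * p**2 * q**2))
    e1_ibd1 = float(np.sum(2 * p**2 * q + 2 * p * q**2))
    e2_ibd1 = float(np.sum(1 - 2 * p**2 * q - 2 * p * q**2))

    rows = []
    ids = gm.samples["id"].to_numpy()
    for i, j in itertools.combinations(range(gm.n_samples), 2):
        frac = m_pair[i, j] / gm.n_variants if gm.n_variants else 0.0
        if frac == 0:
            continue
        p0 = ibs0[i, j] / (e0_ibd0 * frac) if e0_ibd0 > 0 else 0.0
        p1 = (ibs1[i, j] - p0 * e1_ibd0 * frac) / (e1_ibd1 * frac) if e1_ibd1 > 0 else 0.0
        p0, p1 = min(max(p0, 0.0), 1.0), min(max(p1, 0.0), 1.0)
        p2 = (ibs2[i, j] - p0 * e2_ibd0 * frac - p1 * e2_ibd1 * frac) / m_pair[i, j]
        p2 = min(max(p2, 0.0), 1.0)
        total = p0 + p1 + p2
        if total > 0:
            p0, p1, p2 = p0 / total, p1 / total, p2 / total
        pi = p1 / 2 + p2
        rows.append({"id1": ids[i], "id2": ids[j], "pi_hat": pi})
    return pd.DataFrame(rows, columns=["id1", "id2", "pi_hat"])


def prune_related(
    gm: GenotypeMatrix,
    threshold: float = RELATEDNESS_THRESHOLD,
    pairs: pd.DataFrame | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove one member of each related pair (pi_hat >= threshold).

    The member with the lower genotyping call rate goes; on a tie the sample
    with the later (lexicographically greater) id goes. Pairs are processed
    in decreasing pi_hat order so duplicates are resolved first.
    """
    if pairs is None:
        pairs = estimate_relatedness(gm)
    report = QCReport(n_input=gm.n_samples, pi_hat=pairs)
    call_rate = dict(zip(gm.samples["id"], gm.sample_call_rate()))
    removed: set[str] = set()
    flagged = pairs[pairs["pi_hat"] >= threshold].sort_values(
        "pi_hat", ascending=False, kind="stable"
    )
    for _, row in flagged.iterrows():
        a, b = row["id1"], row["id2"]
        if a in removed or b in removed:
            continue
        ca, cb = call_rate[a], call_rate[b]
        if ca < cb:
            removed.add(a)
        elif cb < ca:
            removed.add(b)
        else:
            removed.add(max(a, b))
    report.removed["related"] = sorted(removed)
    keep = ~gm.samples["id"].isin(removed)
    return gm.subset(sample_idx=np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# Principal components
# ---------------------------------------------------------------------------


def compute_pcs(gm: GenotypeMatrix, n_pcs: int = 6) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the standardized dosage matrix.

    Columns are centered at 2*p_hat and scaled by sqrt(2*p_hat*(1-p_hat));
    missing dosages are mean-imputed (zero after centering). Returns the
    orthonormal sample PC coordinates (left singular vectors) and the
    eigenvalues (squared singular values / (n-1)), non-increasing.
    """
    n = gm.n_samples
    if n_pcs > min(n, gm.n_variants):
        raise ValueError(f"n_pcs={n_pcs} exceeds matrix rank bound")
    p = gm.allele_freq()
    keep = (p > 0) & (p < 1) & np.isfinite(p)
    x = gm.dosages[:, keep] - 2 * p[keep]
    x = np.where(np.isnan(x), 0.0, x)
    x /= np.sqrt(2 * p[keep] * (1 - p[keep]))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eigvals = s**2 / (n - 1)
    coords = pd.DataFrame(
        u[:, :n_pcs], columns=[f"PC{i+1}" for i in range(n_pcs)]
    )
    coords.insert(0, "id", gm.samples["id"].to_numpy())
    return coords, eigvals[:n_pcs]
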