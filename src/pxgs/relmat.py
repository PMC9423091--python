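"""Genotype QC, imputation, and relationship matrices.

Builds the four relationship-matrix families used in genomic evaluation of
forest-tree trials:

* ``G``  — realized additive genomic relationship (VanRaden),
* ``Gd`` — realized dominance genomic relationship (Vitezica coding),
* ``A``  — pedigree numerator relationship (tabular method),
* ``Ad`` — pedigree dominance relationship,

together with the marker QC steps (minor-allele-frequency and missingness
filters, mean/EM imputation), matrix comparison, and SNP-class subsetting.

Genotypes are allele dosages of the counted allele, coded 0/1/2 with
``NaN`` for missing calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class DegenerateInputError(ValueError):
    """All informative content was removed (e.g. only monomorphic SNPs)."""


class IntegrityError(ValueError):
    """Inputs are structurally inconsistent (label mismatch, missing data)."""


class PedigreeError(ValueError):
    """Pedigree contains cycles or references unknown individuals."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with missing values as NaN.

    Parameters
    ----------
    sample_ids : array of str
        Row labels, unique.
    snp_ids : array of str
        Column labels, unique.
    dosage : (n_samples, n_snps) float array
        Dosage of the counted allele; integer codes {0, 1, 2} before
        imputation, possibly fractional in [0, 2] after imputation;
        NaN marks a missing call.
    """

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise IntegrityError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise IntegrityError("duplicate sample ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise IntegrityError("duplicate SNP ids")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosage < 0) | (self.dosage > 2))
        if bad:
            raise IntegrityError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    @property
    def allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of the counted allele, from observed calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosage, axis=0) / 2.0

    @property
    def snp_missing_rate(self) -> np.ndarray:
        return self.missing_mask.mean(axis=0)

    @property
    def sample_missing_rate(self) -> np.ndarray:
        return self.missing_mask.mean(axis=1)

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as e:
            raise IntegrityError(f"unknown sample id {e.args[0]!r}") from None

    def subset(self, samples=None, snps=None) -> "GenotypeMatrix":
        rows = slice(None) if samples is None else self.sample_index(samples)
        if snps is None:
            cols = slice(None)
        else:
            lookup = {s: i for i, s in enumerate(self.snp_ids)}
            cols = np.array([lookup[s] for s in snps], dtype=int)
        return GenotypeMatrix(
            self.sample_ids[rows] if samples is not None else self.sample_ids.copy(),
            self.snp_ids[cols] if snps is not None else self.snp_ids.copy(),
            self.dosage[rows][:, cols] if snps is not None else self.dosage[rows].copy(),
        )

    # -- text I/O -----------------------------------------------------------

    def to_dosage_tsv(self, path) -> None:
        df = pd.DataFrame(self.dosage, index=self.sample_ids, columns=self.snp_ids)
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_dosage_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(df.index.to_numpy(object), df.columns.to_numpy(object), df.to_numpy(float))

    def to_vcf(self, path, contig: str = "1") -> None:
        """Write as a minimal GT-only VCF (one contig, positions 1..n_snps).

        Fractional (imputed) dosages cannot be represented and raise.
        """
        d = self.dosage
        ok = np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0))
        if not ok.all():
            raise IntegrityError("VCF output requires integer dosages 0/1/2")
        gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={contig},length={self.n_snps + 1}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(map(str, self.sample_ids))
                + "\n"
            )
            for j, snp in enumerate(self.snp_ids):
                calls = "\t".join(
                    "./." if np.isnan(x) else gt_codes[x] for x in d[:, j]
                )
                fh.write(f"{contig}\t{j + 1}\t{snp}\tA\tC\t.\tPASS\t.\tGT\t{calls}\n")

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read diploid biallelic GT calls from a VCF via cyvcf2.

        The counted allele is the ALT allele; ``./.`` becomes NaN.
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        samples = np.asarray(vcf.samples, dtype=object)
        snp_ids, cols = [], []
        for var in vcf:
            snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
            gt = var.gt_types.astype(float)  # 0=hom ref, 1=het, 2=hom alt, 3=missing
            gt[gt == 3] = np.nan
            cols.append(gt)
        if not cols:
            raise DegenerateInputError("no variants in VCF")
        return cls(samples, np.asarray(snp_ids, dtype=object), np.column_stack(cols))


@dataclass
class RelationshipMatrix:
    """Labeled symmetric relationship matrix.

    ``kind`` is ``"additive"`` or ``"dominance"``; ``source`` is
    ``"pedigree"`` or ``"marker"``; ``snp_class`` optionally records the
    SNP annotation category the matrix was built from.
    """

    ids: np.ndarray
    values: np.ndarray
    kind: str = "additive"
    source: str = "marker"
    snp_class: str | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise IntegrityError("matrix shape does not match ids")
        if not np.all(np.isfinite(self.values)):
            raise IntegrityError("relationship matrix contains non-finite values")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise IntegrityError("relationship matrix is not symmetric")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as e:
            raise IntegrityError(f"id {e.args[0]!r} not in relationship matrix") from None

    def loc(self, i, j) -> float:
        ii, jj = self.index([i])[0], self.index([j])[0]
        return float(self.values[ii, jj])

    def submatrix(self, ids) -> "RelationshipMatrix":
        idx = self.index(ids)
        return replace(self, ids=np.asarray(ids, dtype=object), values=self.values[np.ix_(idx, idx)])

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        df.index.name = "id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, kind="additive", source="marker") -> "RelationshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.index.to_numpy(object), df.to_numpy(float), kind=kind, source=source)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    n_samples_in: int
    n_snps_in: int
    samples_removed_missing: int
    snps_removed_maf: int
    snps_removed_missing: int
    n_samples_out: int
    n_snps_out: int
    removed_sample_ids: list = field(default_factory=list)
    removed_snp_ids: list = field(default_factory=list)


def filter_snps(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    max_snp_missing: float = 0.20,
    max_ind_missing: float = 0.40,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply MAF and missingness filters.

    Individuals with missingness above ``max_ind_missing`` are dropped
    first; SNP minor-allele frequency and missingness are then recomputed
    on the retained individuals, and SNPs failing either rule are dropped.
    """
    for name, v in (("maf_min", maf_min), ("max_snp_missing", max_snp_missing),
                    ("max_ind_missing", max_ind_missing)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")

    keep_rows = g.sample_missing_rate <= max_ind_missing
    removed_samples = list(g.sample_ids[~keep_rows])
    d = g.dosage[keep_rows]
    if d.shape[0] == 0:
        raise DegenerateInputError("all individuals removed by missingness filter")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    maf = np.where(np.isnan(maf), 0.0, maf)  # fully-missing SNP: treat as uninformative
    miss = np.isnan(d).mean(axis=0)
    fail_maf = maf < maf_min
    fail_miss = miss > max_snp_missing
    keep_cols = ~(fail_maf | fail_miss)
    if not keep_cols.any():
        raise DegenerateInputError("all SNPs removed by filters")

    out = GenotypeMatrix(g.sample_ids[keep_rows], g.snp_ids[keep_cols], d[:, keep_cols])
    report = FilterReport(
        n_samples_in=g.n_samples,
        n_snps_in=g.n_snps,
        samples_removed_missing=int((~keep_rows).sum()),
        snps_removed_maf=int(fail_maf.sum()),
        snps_removed_missing=int((fail_miss & ~fail_maf).sum()),
        n_samples_out=out.n_samples,
        n_snps_out=out.n_snps,
        removed_sample_ids=removed_samples,
        removed_snp_ids=list(g.snp_ids[~keep_cols]),
    )
    return out, report


def impute_missing(g: GenotypeMatrix, method: str = "mean", rank: int = 10,
                   tol: float = 1e-6, max_iter: int = 100) -> GenotypeMatrix:
    """Fill missing dosages.

    ``mean`` replaces each missing call with twice the observed allele
    frequency of its SNP.  ``em`` starts from the mean fill and iterates a
    low-rank reconstruction (rank-``rank`` SVD of the column-centered
    matrix) of the missing cells until the relative change falls below
    ``tol``, exploiting between-individual covariance; observed entries are
    never altered.
    """
    mask = g.missing_mask
    if not mask.any():
        return GenotypeMatrix(g.sample_ids.copy(), g.snp_ids.copy(), g.dosage.copy())
    if mask.all(axis=0).any():
        raise IntegrityError("fully missing SNP: filter before imputation")

    mu = 2.0 * g.allele_freq
    d = g.dosage.copy()
    d[mask] = np.broadcast_to(mu, d.shape)[mask]
    if method == "mean":
        return GenotypeMatrix(g.sample_ids.copy(), g.snp_ids.copy(), d)
    if method != "em":
        raise ValueError(f"unknown imputation method {method!r}")

    r = min(rank, g.n_samples - 1, g.n_snps - 1)
    prev = d[mask].copy()
    for _ in range(max_iter):
        col_mean = d.mean(axis=0)
        centered = d - col_mean
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        recon = (u[:, :r] * s[:r]) @ vt[:r] + col_mean
        d[mask] = np.clip(recon[mask], 0.0, 2.0)
        change = np.linalg.norm(d[mask] - prev) / max(np.linalg.norm(prev), 1e-12)
        prev = d[mask].copy()
        if change < tol:
            break
    return GenotypeMatrix(g.sample_ids.copy(), g.snp_ids.copy(), d)


# ---------------------------------------------------------------------------
# marker-based matrices
# ---------------------------------------------------------------------------


def compute_G_additive(g: GenotypeMatrix, snp_class: str | None = None) -> RelationshipMatrix:
    """VanRaden realized additive genomic relationship.

    ``G = W W' / (2 * sum_m p_m (1 - p_m))`` with ``W`` the dosage matrix
    column-centered at twice the allele frequency of the analyzed sample.
    """
    if g.missing_mask.any():
        raise IntegrityError("impute missing genotypes before building G")
    p = g.allele_freq
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0.0:
        raise DegenerateInputError("all SNPs monomorphic; G undefined")
    w = g.dosage - 2.0 * p
    values = (w @ w.T) / denom
    return RelationshipMatrix(g.sample_ids.copy(), values, kind="additive",
                              source="marker", snp_class=snp_class)


def _dominance_coding(dosage: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Vitezica dominance covariate, linearly interpolated between the
    three-point coding h(0) = -2q^2, h(1) = 2pq, h(2) = -2p^2."""
    q = 1.0 - p
    h0, h1, h2 = -2.0 * q**2, 2.0 * p * q, -2.0 * p**2
    x = dosage
    low = np.clip(x, 0.0, 1.0)
    high = np.clip(x - 1.0, 0.0, 1.0)
    return h0 + (h1 - h0) * low + (h2 - h1) * high


def compute_G_dominance(g: GenotypeMatrix, snp_class: str | None = None) -> RelationshipMatrix:
    """Vitezica realized dominance genomic relationship.

    ``Gd = H H' / sum_m (2 p_m q_m)^2`` with H the per-SNP dominance
    covariates; the coding is mean-zero and orthogonal to the additive
    coding under Hardy-Weinberg proportions.
    """
    if g.missing_mask.any():
        raise IntegrityError("impute missing genotypes before building Gd")
    p = g.allele_freq
    denom = np.sum((2.0 * p * (1.0 - p)) ** 2)
    if denom <= 0.0:
        raise DegenerateInputError("all SNPs monomorphic; Gd undefined")
    h = _dominance_coding(g.dosage, p)
    values = (h @ h.T) / denom
    return RelationshipMatrix(g.sample_ids.copy(), values, kind="dominance",
                              source="marker", snp_class=snp_class)


# ---------------------------------------------------------------------------
# pedigree-based matrices
# ---------------------------------------------------------------------------


def _sorted_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    """Topologically sort a pedigree so parents precede offspring."""
    for col in ("id", "mother", "father"):
        if col not in ped.columns:
            raise PedigreeError(f"pedigree table must have column {col!r}")
    ids = ped["id"].tolist()
    if len(set(ids)) != len(ids):
        raise PedigreeError("duplicate individual ids in pedigree")
    known = set(ids)
    for col in ("mother", "father"):
        parents = ped[col].dropna()
        unknown = set(parents) - known
        if unknown:
            raise PedigreeError(f"unknown {col} label(s): {sorted(map(str, unknown))[:5]}")
    placed: dict[str, int] = {}
    rows = ped.set_index("id")
    remaining = list(ids)
    order = []
    while remaining:
        progressed = False
        still = []
        for i in remaining:
            m, f = rows.at[i, "mother"], rows.at[i, "father"]
            if (pd.isna(m) or m in placed) and (pd.isna(f) or f in placed):
                placed[i] = len(order)
                order.append(i)
                progressed = True
            else:
                still.append(i)
        if not progressed:
            raise PedigreeError("pedigree contains a cycle")
        remaining = still
    return ped.set_index("id").loc[order].reset_index()


def compute_A_additive(ped: pd.DataFrame) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    ``ped`` has columns ``id``, ``mother``, ``father`` (NaN/None for
    unknown founders).  Diagonals are ``1 + F``; a missing parent
    contributes zero relationship.
    """
    sp = _sorted_pedigree(ped)
    ids = sp["id"].to_numpy(object)
    n = len(ids)
    pos = {v: k for k, v in enumerate(ids)}
    mi = np.array([pos[m] if pd.notna(m) else -1 for m in sp["mother"]], dtype=int)
    fi = np.array([pos[f] if pd.notna(f) else -1 for f in sp["father"]], dtype=int)
    a = np.zeros((n, n))
    for i in range(n):
        m, f = mi[i], fi[i]
        row = np.zeros(i)
        if m >= 0:
            row += 0.5 * a[m, :i]
        if f >= 0:
            row += 0.5 * a[f, :i]
        a[i, :i] = row
        a[:i, i] = row
        a[i, i] = 1.0 + (0.5 * a[m, f] if (m >= 0 and f >= 0) else 0.0)
    return RelationshipMatrix(ids, a, kind="additive", source="pedigree")


def compute_A_dominance(ped: pd.DataFrame, A: RelationshipMatrix | None = None) -> RelationshipMatrix:
    """Pedigree dominance relationship matrix.

    For non-founders i, j with parents (fi, mi), (fj, mj):
    ``d_ij = 0.25 (a_{fi,fj} a_{mi,mj} + a_{fi,mj} a_{mi,fj})``; pairs
    involving a founder (or an unknown parent) have zero dominance
    relationship, and the diagonal is 1 (non-inbred convention).
    """
    sp = _sorted_pedigree(ped)
    if A is None:
        A = compute_A_additive(ped)
    ids = sp["id"].to_numpy(object)
    aidx = A.index(ids)
    a = A.values[np.ix_(aidx, aidx)]
    pos = {v: k for k, v in enumerate(ids)}
    mi = np.array([pos[m] if pd.notna(m) else -1 for m in sp["mother"]], dtype=int)
    fi = np.array([pos[f] if pd.notna(f) else -1 for f in sp["father"]], dtype=int)
    has_both = (mi >= 0) & (fi >= 0)
    d = np.zeros((len(ids), len(ids)))
    nb = np.flatnonzero(has_both)
    if nb.size:
        f_, m_ = fi[nb], mi[nb]
        d_nb = 0.25 * (a[np.ix_(f_, f_)] * a[np.ix_(m_, m_)]
                       + a[np.ix_(f_, m_)] * a[np.ix_(m_, f_)])
        d[np.ix_(nb, nb)] = d_nb
    np.fill_diagonal(d, 1.0)
    return RelationshipMatrix(ids, d, kind="dominance", source="pedigree")


# ---------------------------------------------------------------------------
# comparison and subsetting
# ---------------------------------------------------------------------------


def matrix_correlation(m1: RelationshipMatrix, m2: RelationshipMatrix) -> float:
    """Pearson correlation between two relationship matrices over the upper
    triangle including the diagonal, after aligning ids."""
    if set(m1.ids) != set(m2.ids):
        raise IntegrityError("relationship matrices cover different id sets")
    v2 = m2.submatrix(m1.ids).values
    iu = np.triu_indices(m1.n)
    return float(np.corrcoef(m1.values[iu], v2[iu])[0, 1])


def subset_by_annotation(
    g: GenotypeMatrix, ann: pd.DataFrame, category: str
) -> tuple[GenotypeMatrix, dict]:
    """Restrict SNP columns to one annotation category.

    ``ann`` has columns ``snp_id`` and ``category``.  Returns the subset
    and a report with the genotype-class proportions (codes 0/1/2, using
    rounded dosages) of the retained columns.
    """
    if ann["snp_id"].duplicated().any():
        raise IntegrityError("annotation table assigns a SNP to multiple categories")
    cats = ann.set_index("snp_id")["category"]
    missing = [s for s in g.snp_ids if s not in cats.index]
    if missing:
        raise IntegrityError(f"unannotated SNP(s): {missing[:5]}")
    keep = [s for s in g.snp_ids if cats[s] == category]
    if not keep:
        raise DegenerateInputError(f"no SNPs in category {category!r}")
    sub = g.subset(snps=keep)
    d = np.round(sub.dosage)
    total = np.isfinite(d).sum()
    report = {
        "category": category,
        "n_snps": sub.n_snps,
        "genotype_proportions": {
            code: float(np.nansum(d == code) / total) for code in (0, 1, 2)
        },
    }
    return sub, report
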