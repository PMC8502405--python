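"""Per-gene orchestration: QC, allele alignment, the six tests, study FDR.

The decorrelated two-stage strategy is implemented here: the burden Wald
statistic is computed in the Cox model with design [s, X] where
s = G @ beta is the eQTL-weighted burden score, and the variance-component
score for tau is computed under a null that *includes* the fitted burden
term (operationalising "without the constraint of theta = 0"), which makes
the two statistics asymptotically independent.  The standalone KM test
(comparison method) keeps the covariates-only null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from iehc.combine import (DEFAULT_RHO_GRID, acat_combine, adapt_combine,
                          combine_all, fisher_combine)
from iehc.cox import (
    DegenerateDesignError,
    SurvivalDataset,
    fit_cox,
    wald_test,
)
from iehc.kernel import km_score_test

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "WeightSet",
    "GeneSet",
    "AssociationResult",
    "IEHCConfig",
    "snp_qc",
    "align_alleles",
    "hwe_pvalue",
    "run_gene",
    "run_study",
    "bh_fdr",
    "EmptyGeneError",
]

_AMBIGUOUS = ({"A", "T"}, {"C", "G"})
_VALID_ALLELES = {"A", "C", "G", "T"}

TEST_NAMES = ("burden", "km", "fisher", "adapt", "optim", "acat")


class EmptyGeneError(ValueError):
    """No SNP survives QC / alignment for this gene."""


@dataclass
class GenotypeMatrix:
    """Hard-call dosages (0/1/2 counts of the effect allele; NaN = missing)."""

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    dosages: np.ndarray
    effect_allele: np.ndarray | None = None
    other_allele: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.snp_ids = np.asarray(self.snp_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("dosage matrix shape does not match ids")
        obs = self.dosages[~np.isnan(self.dosages)]
        # mean-imputed values land strictly inside [0, 2]; raw hard calls are
        # validated to that range here and to {0,1,2} by the file readers
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise ValueError("dosages must lie in [0, 2] or be missing")
        for attr in ("effect_allele", "other_allele"):
            v = getattr(self, attr)
            if v is not None:
                setattr(self, attr, np.asarray(v, dtype=object))

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def allele_freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        af = self.allele_freq()
        return np.minimum(af, 1.0 - af)

    def missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def subset_snps(self, mask_or_ids) -> "GenotypeMatrix":
        if np.asarray(mask_or_ids).dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            pos = {s: i for i, s in enumerate(self.snp_ids)}
            idx = np.array([pos[s] for s in mask_or_ids if s in pos], dtype=int)
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            snp_ids=self.snp_ids[idx],
            dosages=self.dosages[:, idx],
            effect_allele=None if self.effect_allele is None else self.effect_allele[idx],
            other_allele=None if self.other_allele is None else self.other_allele[idx],
        )


@dataclass
class WeightSet:
    """Per-gene eQTL weights: effect size beta of the effect allele per SNP."""

    gene: str
    snp_ids: np.ndarray
    beta: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids)
        self.beta = np.asarray(self.beta, dtype=float)
        self.effect_allele = np.asarray(self.effect_allele, dtype=object)
        self.other_allele = np.asarray(self.other_allele, dtype=object)
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("weights must be finite")


@dataclass
class GeneSet:
    gene: str
    snp_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    chrom: str | None = None
    start: int | None = None   # 1-based inclusive
    end: int | None = None

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids)
        if self.snp_ids.size != len(set(self.snp_ids.tolist())):
            raise ValueError(f"duplicate SNP ids in gene set {self.gene}")


@dataclass
class AssociationResult:
    gene: str
    s_used: int
    u_theta: float
    u_tau: float
    p_burden: float
    p_km: float
    p_tau: float
    p_fisher: float
    p_adapt: float
    p_optim: float
    p_acat: float
    rho_selected: float
    degenerate_burden: bool = False
    skip_reason: str | None = None


@dataclass
class IEHCConfig:
    """Study-level knobs; QC defaults mirror common GWAS practice."""

    maf_min: float = 0.01
    miss_max: float = 0.05
    hwe_alpha: float = 1e-4
    rho_grid: tuple = DEFAULT_RHO_GRID
    standardize_covariates: bool = True
    ties: str = "efron"
    alpha: float = 0.05
    fdr_level: float = 0.1


def hwe_pvalue(n0: int, n1: int, n2: int) -> float:
    """1-df Pearson chi-square test of Hardy-Weinberg proportions.

    (n0, n1, n2) are genotype counts for 0/1/2 copies of the effect allele.
    """
    n = n0 + n1 + n2
    if n == 0:
        return 1.0
    p = (2 * n2 + n1) / (2 * n)
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    obs = np.array([n0, n1, n2], dtype=float)
    nz = exp > 0
    stat = float(np.sum((obs[nz] - exp[nz]) ** 2 / exp[nz]))
    return float(stats.chi2.sf(stat, df=1))


def snp_qc(
    G: GenotypeMatrix,
    maf_min: float = 0.01,
    miss_max: float = 0.05,
    hwe_alpha: float = 1e-4,
) -> GenotypeMatrix:
    """Filter SNPs by MAF, missingness and HWE; mean-impute the survivors.

    Returns a (possibly empty) matrix; remaining missing dosages are
    replaced by the per-SNP mean so downstream algebra sees no NaNs.
    """
    maf = G.maf()
    miss = G.missingness()
    hwe = np.ones(G.n_snps)
    for j in range(G.n_snps):
        g = G.dosages[:, j]
        g = g[~np.isnan(g)]
        if g.size:
            hwe[j] = hwe_pvalue(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
    keep = (maf >= maf_min) & (miss <= miss_max) & (hwe >= hwe_alpha) & ~np.isnan(maf)
    dropped = G.n_snps - int(keep.sum())
    if dropped:
        logger.info("snp_qc: removed %d/%d SNPs", dropped, G.n_snps)
    out = G.subset_snps(keep)
    if out.dosages.size and np.isnan(out.dosages).any():
        d = out.dosages.copy()
        col_mean = np.nanmean(d, axis=0)
        ii, jj = np.nonzero(np.isnan(d))
        d[ii, jj] = col_mean[jj]
        out = replace(out, dosages=d)
    return out


def _is_ambiguous(a1: str, a2: str) -> bool:
    return {a1, a2} in _AMBIGUOUS


def align_alleles(G: GenotypeMatrix, W: WeightSet) -> tuple[GenotypeMatrix, WeightSet]:
    """Intersect SNPs and harmonise weight orientation to the genotype coding.

    Strand-ambiguous (A/T, C/G) and allele-mismatched SNPs are dropped.
    Where effect/other labels are swapped between the two sources the
    weight's beta is negated and its labels swapped, which is equivalent to
    recoding the dosage as 2 - g up to a subject-constant shift of the
    burden score (irrelevant in a Cox model).  On output the weight effect
    alleles match the genotype effect alleles exactly.
    """
    gpos = {s: i for i, s in enumerate(G.snp_ids)}
    wpos = {s: i for i, s in enumerate(W.snp_ids)}
    shared = [s for s in G.snp_ids if s in wpos]
    if not shared:
        raise EmptyGeneError(f"no overlapping SNPs for gene {W.gene}")
    if G.effect_allele is None:
        logger.warning("genotypes carry no allele labels; trusting weight orientation")
        gi = np.array([gpos[s] for s in shared])
        wi = np.array([wpos[s] for s in shared])
        return G.subset_snps(np.asarray(shared)), WeightSet(
            W.gene, np.asarray(shared), W.beta[wi], W.effect_allele[wi], W.other_allele[wi]
        )
    keep_g, beta, ea, oa, kept_ids = [], [], [], [], []
    for s in shared:
        i, j = gpos[s], wpos[s]
        gea, goa = str(G.effect_allele[i]), str(G.other_allele[i])
        wea, woa = str(W.effect_allele[j]), str(W.other_allele[j])
        if not ({gea, goa} <= _VALID_ALLELES and {wea, woa} <= _VALID_ALLELES):
            continue
        if _is_ambiguous(gea, goa) or _is_ambiguous(wea, woa):
            continue
        if (gea, goa) == (wea, woa):
            b = W.beta[j]
        elif (gea, goa) == (woa, wea):
            b = -W.beta[j]
        else:
            continue
        keep_g.append(i)
        kept_ids.append(s)
        beta.append(b)
        ea.append(gea)
        oa.append(goa)
    if not keep_g:
        raise EmptyGeneError(f"no alignable SNPs for gene {W.gene}")
    mask = np.zeros(G.n_snps, dtype=bool)
    mask[keep_g] = True
    Gs = G.subset_snps(mask)
    Ws = WeightSet(W.gene, np.asarray(kept_ids), np.asarray(beta), np.asarray(ea), np.asarray(oa))
    return Gs, Ws


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, in (0, 1])."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _prepare_covariates(pheno: SurvivalDataset, standardize: bool) -> np.ndarray:
    X = pheno.covariates
    if X.shape[1] == 0 or not standardize:
        return X
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d constant covariate column(s)", (~keep).sum())
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return Xs


def run_gene(
    G: GenotypeMatrix,
    W: WeightSet,
    pheno: SurvivalDataset,
    config: IEHCConfig | None = None,
) -> AssociationResult:
    """All six tests for one gene on aligned, QC'd inputs.

    Monomorphic genotype columns are dropped (with a log entry) before the
    kernel is formed; a constant burden score (e.g. all-zero weights)
    yields p = 1 for the burden and joint tests with a degeneracy flag,
    while the plain KM test still runs on the covariates-only null.
    """
    config = config or IEHCConfig()
    if G.n != pheno.n:
        raise ValueError("genotype and phenotype cohorts differ in size")
    mono = np.ptp(np.nan_to_num(G.dosages), axis=0) == 0
    if mono.any():
        logger.info("gene %s: dropping %d monomorphic SNP(s)", W.gene, mono.sum())
        keep_ids = G.snp_ids[~mono]
        G = G.subset_snps(~mono)
        wkeep = np.isin(W.snp_ids, keep_ids)
        W = WeightSet(W.gene, W.snp_ids[wkeep], W.beta[wkeep],
                      W.effect_allele[wkeep], W.other_allele[wkeep])
    if G.n_snps == 0:
        raise EmptyGeneError(f"gene {W.gene}: no polymorphic SNPs")

    X = _prepare_covariates(pheno, config.standardize_covariates)
    Gd = G.dosages
    order = {s: i for i, s in enumerate(G.snp_ids)}
    widx = np.array([order[s] for s in W.snp_ids])
    beta = np.zeros(G.n_snps)
    beta[widx] = W.beta
    s = Gd @ beta

    # plain KM test: covariates-only null
    fit0 = fit_cox(pheno, X if X.shape[1] else None, ties=config.ties)
    km_plain = km_score_test(pheno, fit0, X if X.shape[1] else None, Gd)

    degenerate = bool(np.ptp(s) < 1e-12)
    if degenerate:
        logger.warning("gene %s: degenerate burden score", W.gene)
        ones = 1.0
        res = AssociationResult(
            gene=W.gene, s_used=G.n_snps, u_theta=0.0, u_tau=km_plain.Q,
            p_burden=ones, p_km=km_plain.p_value, p_tau=ones, p_fisher=ones,
            p_adapt=ones, p_optim=ones, p_acat=acat_combine(
                [1.0, km_plain.p_value, 1.0, 1.0, 1.0]),
            rho_selected=float("nan"), degenerate_burden=True,
        )
        return res

    design = np.column_stack([s, X]) if X.shape[1] else s[:, None]
    fit1 = fit_cox(pheno, design, ties=config.ties)
    u_theta, p_burden = wald_test(fit1, 0)

    # decorrelated variance-component test: burden term in the null
    km_dec = km_score_test(pheno, fit1, design, Gd)
    p_tau = km_dec.p_value

    if km_dec.eigenvalues.size:
        comb = combine_all(p_burden, p_tau, u_theta, km_dec, config.rho_grid)
        p_fisher, p_adapt = comb.p_fisher, comb.p_adapt
        p_optim, rho_sel = comb.p_optim, comb.rho_selected
    else:
        p_fisher = fisher_combine(p_burden, p_tau)
        p_adapt = adapt_combine(p_burden, p_tau)
        p_optim, rho_sel = p_burden, 1.0
    p_acat = acat_combine([p_burden, km_plain.p_value, p_fisher, p_adapt, p_optim])

    return AssociationResult(
        gene=W.gene, s_used=G.n_snps, u_theta=u_theta, u_tau=km_dec.Q,
        p_burden=p_burden, p_km=km_plain.p_value, p_tau=p_tau,
        p_fisher=p_fisher, p_adapt=p_adapt, p_optim=p_optim, p_acat=p_acat,
        rho_selected=rho_sel,
    )


def run_study(
    genes: list[GeneSet],
    G: GenotypeMatrix,
    weights: dict[str, WeightSet],
    pheno: SurvivalDataset,
    config: IEHCConfig | None = None,
) -> pd.DataFrame:
    """Run every gene, never aborting the study for one bad gene.

    Returns one row per gene (input order) with the six p-values and BH
    q-values per test column; genes failing QC keep NA p-values with a
    recorded skip reason.
    """
    config = config or IEHCConfig()
    # sample intersection, genotype rows reordered to the phenotype
    common = [i for i, sid in enumerate(G.sample_ids) if sid in set(pheno.subject_id.tolist())]
    if len(common) < G.n:
        logger.info("sample intersection: %d of %d genotype samples retained",
                    len(common), G.n)
    gmap = {sid: i for i, sid in enumerate(G.sample_ids)}
    rows = []
    ok = np.array([sid in gmap for sid in pheno.subject_id])
    if not ok.all():
        pheno = SurvivalDataset(
            subject_id=pheno.subject_id[ok], time=pheno.time[ok],
            status=pheno.status[ok], covariates=pheno.covariates[ok],
            covariate_names=pheno.covariate_names,
        )
    ridx = np.array([gmap[sid] for sid in pheno.subject_id])

    for gs in genes:
        try:
            Gg = G.subset_snps(gs.snp_ids)
            if Gg.n_snps == 0:
                raise EmptyGeneError(f"gene {gs.gene}: no SNPs found in genotypes")
            Gg = GenotypeMatrix(
                sample_ids=G.sample_ids[ridx], snp_ids=Gg.snp_ids,
                dosages=Gg.dosages[ridx],
                effect_allele=Gg.effect_allele, other_allele=Gg.other_allele,
            )
            Gg = snp_qc(Gg, config.maf_min, config.miss_max, config.hwe_alpha)
            if Gg.n_snps == 0:
                raise EmptyGeneError(f"gene {gs.gene}: all SNPs removed by QC")
            if gs.gene not in weights:
                raise EmptyGeneError(f"gene {gs.gene}: no weights available")
            Gg, Wg = align_alleles(Gg, weights[gs.gene])
            res = run_gene(Gg, Wg, pheno, config)
        except (EmptyGeneError, DegenerateDesignError) as exc:
            logger.warning("skipping gene %s: %s", gs.gene, exc)
            res = AssociationResult(
                gene=gs.gene, s_used=0, u_theta=np.nan, u_tau=np.nan,
                p_burden=np.nan, p_km=np.nan, p_tau=np.nan, p_fisher=np.nan,
                p_adapt=np.nan, p_optim=np.nan, p_acat=np.nan,
                rho_selected=np.nan, skip_reason=str(exc),
            )
        rows.append(res)

    df = pd.DataFrame(
        {
            "gene": [r.gene for r in rows],
            "S": [r.s_used for r in rows],
            **{f"p_{t}": [getattr(r, f"p_{t}") for r in rows] for t in TEST_NAMES},
            "skip_reason": [r.skip_reason for r in rows],
        }
    )
    for t in TEST_NAMES:
        q = np.full(len(df), np.nan)
        mask = df[f"p_{t}"].notna().to_numpy()
        if mask.any():
            q[mask] = bh_fdr(df.loc[mask, f"p_{t}"].to_numpy())
        df[f"q_{t}"] = q
    return df
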