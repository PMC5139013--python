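"""Differential ASE via beta-binomial likelihood-ratio tests.

Per SNP, the per-individual REF counts out of REF+ALT totals are modelled as
beta-binomial with mean ``mu`` (the true reference ratio) and intraclass
correlation ``rho`` (between-individual overdispersion).  A 1-df LRT compares
a common ``mu`` against group-specific means with a shared ``rho`` — the
groups being either a binary clinical label (e.g. postoperative AF vs none)
or paired timepoints (baseline vs post-ischemia, each individual
contributing both).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, gammaln
from scipy.stats import chi2

from .calling import bh_adjust, ref_ratio

log = logging.getLogger(__name__)

__all__ = [
    "BetaBinomialModel",
    "DifferentialAseResult",
    "betabinom_loglik",
    "fit_betabinom",
    "lrt_group_differential",
    "lrt_paired_differential",
    "differential_table",
]

MU_CLAMP = 1e-6    # MLE of mu is evaluated on [MU_CLAMP, 1 - MU_CLAMP]
RHO_MAX = 0.999


@dataclass
class BetaBinomialModel:
    mu: float
    rho: float
    loglik: float
    converged: bool = True
    rho_pinned: bool = False  # single record: rho not estimable, fixed at 0


@dataclass
class DifferentialAseResult:
    snp_id: str
    n_het_group1: int
    n_het_group2: int
    reads_total: int
    ratio_group1: float
    ratio_group2: float
    lrt_stat: float
    p_raw: float
    p_fdr: float = float("nan")
    low_confidence: bool = False  # a group with a single heterozygote
    converged: bool = True


def betabinom_loglik(ref, total, mu: float, rho: float) -> float:
    """Beta-binomial log-likelihood with mean/correlation parameterisation.

    ``rho`` = 0 reduces exactly to the binomial log-likelihood.  Closed
    boundaries (mu in {0, 1} or rho = 1) are errors; callers clamp.
    """
    ref = np.asarray(ref, dtype=int)
    total = np.asarray(total, dtype=int)
    if np.any(total < 1):
        raise ValueError("totals must be >= 1")
    if not (0.0 < mu < 1.0):
        raise ValueError(f"mu must lie strictly in (0, 1), got {mu}")
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"rho must lie in [0, 1), got {rho}")
    logc = gammaln(total + 1) - gammaln(ref + 1) - gammaln(total - ref + 1)
    if rho < 1e-10:
        # binomial limit; below this the concentration (1-rho)/rho is so large
        # that the gammaln differences cancel catastrophically
        return float((logc + ref * np.log(mu) + (total - ref) * np.log1p(-mu)).sum())
    a = mu * (1.0 - rho) / rho
    b = (1.0 - mu) * (1.0 - rho) / rho
    return float((logc + betaln(ref + a, total - ref + b) - betaln(a, b)).sum())


def _negloglik_factory(ref, total, n_groups: int, group_idx):
    """Negative log-likelihood over (mus..., rho); rho is shared across
    groups and may sit on its lower bound 0 (binomial limit)."""
    masks = [group_idx == g for g in range(n_groups)]

    def nll(params):
        rho = float(params[-1])
        ll = 0.0
        for g in range(n_groups):
            m = masks[g]
            ll += betabinom_loglik(ref[m], total[m], float(params[g]), rho)
        return -ll

    return nll


def _moment_rho(ref, total) -> float:
    """Crude starting value for rho from the excess variance of per-record
    ratios; clipped well inside the feasible region."""
    if len(ref) < 2 or total.sum() == 0:
        return 1e-3
    pi = ref.sum() / total.sum()
    if not (0 < pi < 1):
        return 1e-3
    chi2_stat = (((ref - pi * total) ** 2) / (pi * (1 - pi) * total)).sum()
    denom = max((total - 1).sum(), 1)
    return float(np.clip((chi2_stat - len(ref)) / denom, 1e-3, 0.5))


def fit_betabinom(
    ref,
    total,
    groups=None,
    rho_fixed: float | None = None,
) -> BetaBinomialModel | tuple[list[BetaBinomialModel], float]:
    """Maximum-likelihood beta-binomial fit.

    With ``groups`` None a single (mu, rho) is fitted and one model returned.
    With an integer group vector, group-specific means share a common rho;
    the per-group models and the shared rho are returned, with the joint
    log-likelihood split per group.  A single record pins rho at 0 (not
    estimable) and sets the model flag.  ``rho_fixed`` holds rho at a given
    value instead of estimating it (0 gives the pure-binomial LRT).
    """
    ref = np.asarray(ref, dtype=int)
    total = np.asarray(total, dtype=int)
    if len(ref) == 0:
        raise ValueError("at least one record required")
    if groups is None:
        group_idx = np.zeros(len(ref), dtype=int)
        n_groups = 1
    else:
        group_idx = np.asarray(groups, dtype=int)
        n_groups = int(group_idx.max()) + 1
        for g in range(n_groups):
            if not np.any(group_idx == g):
                raise ValueError(f"group {g} has no records")

    if len(ref) == 1:
        mu = float(np.clip(ref[0] / total[0], MU_CLAMP, 1 - MU_CLAMP))
        ll = betabinom_loglik(ref, total, mu, 0.0)
        model = BetaBinomialModel(mu=mu, rho=0.0, loglik=ll, rho_pinned=True)
        return model if groups is None else ([model], 0.0)

    mus0 = []
    for g in range(n_groups):
        m = group_idx == g
        mus0.append(np.clip(ref[m].sum() / max(total[m].sum(), 1), MU_CLAMP, 1 - MU_CLAMP))
    rho0 = _moment_rho(ref, total)
    nll = _negloglik_factory(ref, total, n_groups, group_idx)

    if rho_fixed is not None:
        bounds = [(MU_CLAMP, 1 - MU_CLAMP)] * n_groups + [(rho_fixed, rho_fixed)]
        rho0 = rho_fixed
    else:
        bounds = [(MU_CLAMP, 1 - MU_CLAMP)] * n_groups + [(0.0, RHO_MAX)]
    best = None
    for rho_start in (rho0, 0.1 if rho_fixed is None else rho0):
        x0 = np.array([*mus0, rho_start])
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
        if best.success:  # second start only rescues a failed first fit
            break
    converged = bool(best.success)
    x_best, f_best = best.x, float(best.fun)
    if not converged:
        # L-BFGS-B line searches often terminate "abnormally" on the flat
        # boundary rho -> 0; a derivative-free polish decides whether the
        # iterate was already at the optimum
        lo = np.array([MU_CLAMP] * n_groups + [rho_fixed if rho_fixed is not None else 0.0])
        hi = np.array([1 - MU_CLAMP] * n_groups + [rho_fixed if rho_fixed is not None else RHO_MAX])
        polish = minimize(lambda x: nll(np.clip(x, lo, hi)), x_best,
                          method="Nelder-Mead",
                          options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 1000})
        if polish.fun <= f_best:
            x_best = np.clip(polish.x, lo, hi)
            improvement = f_best - float(polish.fun)
            f_best = float(polish.fun)
            converged = improvement < 1e-3 or polish.success
    if not converged:
        log.warning("beta-binomial fit did not fully converge (ll=%.4f)", -f_best)
    mus = np.clip(x_best[:n_groups], MU_CLAMP, 1 - MU_CLAMP)
    rho = float(np.clip(x_best[-1], 0.0, RHO_MAX))
    if groups is None:
        return BetaBinomialModel(
            mu=float(mus[0]), rho=rho, loglik=-f_best, converged=converged
        )
    models = []
    for g in range(n_groups):
        m = group_idx == g
        models.append(
            BetaBinomialModel(
                mu=float(mus[g]), rho=rho,
                loglik=betabinom_loglik(ref[m], total[m], float(mus[g]), rho),
                converged=converged,
            )
        )
    return models, rho


def _lrt(ref, total, group_idx, rho_fixed=None) -> tuple[float, float, bool]:
    """1-df LRT of group-specific vs common mean, shared rho."""
    null = fit_betabinom(ref, total, rho_fixed=rho_fixed)
    models, _ = fit_betabinom(ref, total, groups=group_idx, rho_fixed=rho_fixed)
    ll_full = sum(m.loglik for m in models)
    stat = max(0.0, 2.0 * (ll_full - null.loglik))
    p = float(chi2.sf(stat, df=1))
    converged = null.converged and all(m.converged for m in models)
    return stat, p, converged


def lrt_group_differential(records: pd.DataFrame, snp_id: str = "",
                           rho_fixed: float | None = None) -> DifferentialAseResult:
    """Differential ASE between two unpaired groups for one SNP.

    ``records`` needs columns ref_count, alt_count, group with exactly two
    group labels (sorted order defines group1/group2) and at least one
    heterozygote per group.  OTHER reads are excluded from the totals.
    """
    labels = sorted(records["group"].unique())
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    ref = records["ref_count"].to_numpy(dtype=int)
    total = ref + records["alt_count"].to_numpy(dtype=int)
    if np.any(total < 1):
        records = records[total >= 1]
        ref = records["ref_count"].to_numpy(dtype=int)
        total = ref + records["alt_count"].to_numpy(dtype=int)
    group_idx = (records["group"].to_numpy() == labels[1]).astype(int)
    if not (np.any(group_idx == 0) and np.any(group_idx == 1)):
        raise ValueError("each group needs at least one heterozygote with reads")
    stat, p, converged = _lrt(ref, total, group_idx, rho_fixed=rho_fixed)
    n1, n2 = int((group_idx == 0).sum()), int((group_idx == 1).sum())
    r1 = ref_ratio(int(ref[group_idx == 0].sum()), int((total - ref)[group_idx == 0].sum()))
    r2 = ref_ratio(int(ref[group_idx == 1].sum()), int((total - ref)[group_idx == 1].sum()))
    return DifferentialAseResult(
        snp_id=snp_id, n_het_group1=n1, n_het_group2=n2, reads_total=int(total.sum()),
        ratio_group1=r1, ratio_group2=r2, lrt_stat=stat, p_raw=p,
        low_confidence=min(n1, n2) == 1, converged=converged,
    )


def lrt_paired_differential(records: pd.DataFrame, snp_id: str = "") -> DifferentialAseResult:
    """Differential ASE between paired timepoints for one SNP.

    ``records`` needs columns ref_count, alt_count, timepoint ("baseline" /
    "post") and individual_id; individuals missing either timepoint are
    dropped (logged).  Timepoint enters as a fixed effect with a shared rho —
    both timepoints of an individual condition on the same heterozygous
    genotype, so the allelic ratio is directly comparable within a pair.
    """
    tps = set(records["timepoint"])
    if not tps <= {"baseline", "post"}:
        raise ValueError(f"timepoints must be baseline/post, got {sorted(tps)}")
    complete = records.groupby("individual_id")["timepoint"].nunique()
    keep = set(complete.index[complete == 2])
    dropped = set(records["individual_id"]) - keep
    if dropped:
        log.info("%s: dropping %d individuals missing a timepoint", snp_id, len(dropped))
    records = records[records["individual_id"].isin(keep)]
    if records.empty:
        raise ValueError("no individual has both timepoints")
    renamed = records.rename(columns={"timepoint": "group"})
    res = lrt_group_differential(renamed, snp_id=snp_id)
    return res


def differential_table(
    counts: pd.DataFrame,
    label_column: str,
    paired: bool = False,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the LRT SNP by SNP over a long count table and BH-adjust.

    ``label_column`` holds the binary label ("group" for clinical groups or
    "timepoint" for paired designs).  SNPs that cannot be tested (a group
    with no heterozygote, or no complete pair) are skipped and logged.
    """
    rows = []
    for sid, grp in counts.groupby("snp_id", sort=True):
        try:
            if paired:
                res = lrt_paired_differential(grp, snp_id=sid)
            else:
                res = lrt_group_differential(
                    grp.rename(columns={label_column: "group"}), snp_id=sid
                )
        except ValueError as exc:
            log.info("skipping %s: %s", sid, exc)
            continue
        rows.append(res)
    if not rows:
        return pd.DataFrame(
            columns=["snp_id", "n_het_group1", "n_het_group2", "reads_total",
                     "ratio_group1", "ratio_group2", "lrt_stat", "p_raw", "p_fdr",
                     "low_confidence", "converged", "significant"]
        )
    out = pd.DataFrame([r.__dict__ for r in rows])
    out["p_fdr"] = bh_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["p_fdr"] < fdr_alpha
    return out.sort_values(["p_raw", "snp_id"], kind="mergesort").reset_index(drop=True)
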