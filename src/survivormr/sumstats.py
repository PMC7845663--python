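"""GWAS-style summary statistics: scans, I/O, harmonization, pruning.

Per-variant association scans turn a (survivor-selected) cohort into the
two-sample interchange format of summary-statistics MR: one row per variant
with effect/other allele, effect-allele frequency, beta, standard error,
Wald p-value and sample size.  Binary traits are scanned with per-variant
logistic regression (beta on the log-odds scale), continuous traits with
per-variant ordinary least squares, both unadjusted — as public GWAS summary
statistics would be from this package's point of view.

Harmonization re-expresses every study's estimates on a single shared effect
allele per variant, flipping sign and frequency where the allele labels are
swapped, resolving strand flips by complement, and resolving palindromic
(A/T, C/G) variants by allele-frequency proximity when frequencies are
informative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .simulate import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "VariantAssociation",
    "SummaryStatsTable",
    "HarmonizedDataset",
    "association_scan",
    "harmonize",
    "harmonize_tables",
    "prune_instruments",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: below this distance from 0.5, allele frequency cannot orient a palindromic variant
PALINDROME_EAF_MARGIN = 0.08


@dataclass
class VariantAssociation:
    """One variant's effect on one trait, with allele metadata."""

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int
    trait_id: str = ""

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be > 0")
        if not (0.0 < self.eaf < 1.0):
            raise ValueError("eaf must lie in (0, 1)")
        if not (0.0 <= self.pval <= 1.0):
            raise ValueError("pval must lie in [0, 1]")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele must differ")


class SummaryStatsTable:
    """Ordered per-variant associations for a single trait.

    Thin wrapper over a :class:`pandas.DataFrame` with the fixed column set
    ``variant_id, effect_allele, other_allele, eaf, beta, se, pval, n`` plus a
    trait id and a provenance (sample) label used to track two-sample designs.
    """

    COLUMNS = ["variant_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]

    def __init__(self, df: pd.DataFrame, trait_id: str = "", sample_id: str = ""):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"summary-statistics table missing columns: {missing}")
        df = df.loc[:, self.COLUMNS].reset_index(drop=True)
        if df["variant_id"].duplicated().any():
            dupes = df.loc[df["variant_id"].duplicated(), "variant_id"].tolist()
            raise ValueError(f"duplicate variant ids in table: {dupes}")
        if (df["se"] <= 0).any():
            raise ValueError("all standard errors must be > 0")
        if ((df["eaf"] <= 0) | (df["eaf"] >= 1)).any():
            raise ValueError("all effect-allele frequencies must lie in (0, 1)")
        self.df = df
        self.trait_id = trait_id
        self.sample_id = sample_id

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> list[str]:
        return self.df["variant_id"].tolist()

    @classmethod
    def from_records(cls, records: list[VariantAssociation], trait_id: str = "",
                     sample_id: str = "") -> "SummaryStatsTable":
        df = pd.DataFrame([{
            "variant_id": r.variant_id, "effect_allele": r.effect_allele,
            "other_allele": r.other_allele, "eaf": r.eaf, "beta": r.beta,
            "se": r.se, "pval": r.pval, "n": r.n,
        } for r in records])
        return cls(df, trait_id=trait_id or (records[0].trait_id if records else ""),
                   sample_id=sample_id)

    def write_tsv(self, path) -> None:
        """Tab-separated text with the fixed header; missing values as NA."""
        self.df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")

    @classmethod
    def read_tsv(cls, path, trait_id: str = "", sample_id: str = "") -> "SummaryStatsTable":
        """Read a tab-separated table; columns are matched by name, any order."""
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        return cls(df, trait_id=trait_id, sample_id=sample_id)


@dataclass
class HarmonizedDataset:
    """Allele-aligned effect matrices for MR: rows = variants, columns = exposures."""

    variant_ids: list[str]
    bx: np.ndarray
    se_bx: np.ndarray
    by: np.ndarray
    se_by: np.ndarray
    exposure_ids: list[str]

    def __post_init__(self) -> None:
        self.bx = np.atleast_2d(np.asarray(self.bx, dtype=float))
        self.se_bx = np.atleast_2d(np.asarray(self.se_bx, dtype=float))
        if self.bx.shape[0] == 1 and len(self.variant_ids) > 1:
            self.bx = self.bx.T
            self.se_bx = self.se_bx.T
        self.by = np.asarray(self.by, dtype=float)
        self.se_by = np.asarray(self.se_by, dtype=float)
        k = len(self.variant_ids)
        K = len(self.exposure_ids)
        if self.bx.shape != (k, K) or self.se_bx.shape != (k, K):
            raise ValueError("bx / se_bx shapes inconsistent with variant and exposure lists")
        if self.by.shape != (k,) or self.se_by.shape != (k,):
            raise ValueError("by / se_by must be length-k vectors")
        if np.any(self.se_bx <= 0) or np.any(self.se_by <= 0):
            raise ValueError("all standard errors must be > 0")

    @property
    def k(self) -> int:
        return len(self.variant_ids)

    @property
    def K(self) -> int:
        return len(self.exposure_ids)

    def subset(self, variant_ids: list[str]) -> "HarmonizedDataset":
        """Row subset in the order given; unknown ids raise ``KeyError``."""
        pos = {v: i for i, v in enumerate(self.variant_ids)}
        idx = np.array([pos[v] for v in variant_ids])
        return HarmonizedDataset(list(variant_ids), self.bx[idx], self.se_bx[idx],
                                 self.by[idx], self.se_by[idx], list(self.exposure_ids))

    def select_exposures(self, exposure_ids: list[str]) -> "HarmonizedDataset":
        pos = {e: j for j, e in enumerate(self.exposure_ids)}
        idx = np.array([pos[e] for e in exposure_ids])
        return HarmonizedDataset(list(self.variant_ids), self.bx[:, idx],
                                 self.se_bx[:, idx], self.by, self.se_by,
                                 list(exposure_ids))


def _resolve_trait(cohort: Cohort, trait: str | np.ndarray) -> tuple[np.ndarray, str]:
    if isinstance(trait, str):
        if trait in ("x", "y", "y2", "u1", "u2"):
            return np.asarray(getattr(cohort, trait), dtype=float), trait
        if trait in cohort.traits:
            return np.asarray(cohort.traits[trait], dtype=float), trait
        raise KeyError(f"unknown trait {trait!r}")
    return np.asarray(trait, dtype=float), "trait"


def _linear_scan(g: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant OLS slope of trait on dose, closed form."""
    n = g.shape[0]
    gc = g - g.mean(axis=0)
    vc = v - v.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = gc.T @ vc
    beta = sxy / sxx
    syy = float(vc @ vc)
    rss = syy - beta * sxy
    sigma2 = np.maximum(rss, 0.0) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    pval = 2.0 * norm.sf(np.abs(beta / se))
    return beta, se, pval


def _logistic_scan(
    g: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 60
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant logistic regression of y on dose, vectorized Newton (IRLS).

    Each variant gets its own (intercept, slope) fit by maximum likelihood;
    iteration stops when the max absolute score falls below ``tol``.  Returns
    (beta, se, pval, converged-mask); separation is flagged as non-convergence.
    """
    n, m = g.shape
    a = np.full(m, float(np.log(y.mean() / (1 - y.mean()))))
    b = np.zeros(m)
    ones = np.ones(n)
    converged = np.zeros(m, dtype=bool)
    for _ in range(max_iter):
        eta = a[None, :] + g * b[None, :]
        p = expit(eta)
        r = y[:, None] - p
        g1 = ones @ r
        g2 = np.einsum("ij,ij->j", g, r)
        w = p * (1.0 - p)
        h11 = ones @ w
        h12 = np.einsum("ij,ij->j", g, w)
        h22 = np.einsum("ij,ij,ij->j", g, g, w)
        det = h11 * h22 - h12 * h12
        det = np.where(det <= 0, np.nan, det)
        da = (h22 * g1 - h12 * g2) / det
        db = (h11 * g2 - h12 * g1) / det
        # freeze already-converged fits to keep results deterministic
        da = np.where(converged, 0.0, da)
        db = np.where(converged, 0.0, db)
        a = a + np.nan_to_num(da)
        b = b + np.nan_to_num(db)
        converged = converged | (
            (np.abs(g1) < tol * n) & (np.abs(g2) < tol * n) & np.isfinite(da) & np.isfinite(db)
        )
        if converged.all():
            break
    # SE from the observed information at the solution
    eta = a[None, :] + g * b[None, :]
    w = expit(eta) * (1.0 - expit(eta))
    h11 = ones @ w
    h12 = np.einsum("ij,ij->j", g, w)
    h22 = np.einsum("ij,ij,ij->j", g, g, w)
    det = h11 * h22 - h12 * h12
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.where(det > 0, h11 / det, np.nan))
    ok = converged & np.isfinite(se) & (np.abs(b) < 15.0)
    pval = 2.0 * norm.sf(np.abs(b / se))
    return b, se, pval, ok


def association_scan(
    cohort: Cohort,
    trait: str | np.ndarray,
    model: str,
    sample_id: str = "",
) -> SummaryStatsTable:
    """Scan every variant for association with one trait.

    ``model`` is ``"linear"`` (continuous trait, OLS slope per allele) or
    ``"logistic"`` (binary trait, log-odds per allele via IRLS to 1e-8).
    Monomorphic variants are dropped; logistic fits that fail to converge or
    show separation are dropped with a logged warning — as a real GWAS
    pipeline would flag them.
    """
    if cohort.n < 3:
        raise ValueError("cohort too small to scan")
    values, trait_name = _resolve_trait(cohort, trait)
    uniq = np.unique(values)
    if model == "logistic":
        if not np.isin(uniq, [0.0, 1.0]).all():
            raise ValueError("logistic scan requires a binary 0/1 trait")
    elif model == "linear":
        if uniq.size <= 2 and np.isin(uniq, [0.0, 1.0]).all():
            raise ValueError("linear scan requires a continuous trait")
    else:
        raise ValueError("model must be 'linear' or 'logistic'")

    g = cohort.genotypes.astype(float)
    poly = g.std(axis=0) > 0
    if not poly.all():
        dropped = [v for v, keep in zip(cohort.variant_ids, poly) if not keep]
        logger.warning("dropping monomorphic variants: %s", dropped)
    g = g[:, poly]
    ids = [v for v, keep in zip(cohort.variant_ids, poly) if keep]
    ea = [v for v, keep in zip(cohort.effect_alleles, poly) if keep]
    oa = [v for v, keep in zip(cohort.other_alleles, poly) if keep]

    if model == "linear":
        beta, se, pval = _linear_scan(g, values)
        ok = np.isfinite(beta) & np.isfinite(se) & (se > 0)
    else:
        beta, se, pval, ok = _logistic_scan(g, values.astype(float))
        if not ok.all():
            bad = [v for v, o in zip(ids, ok) if not o]
            logger.warning("dropping non-converged/separated logistic fits: %s", bad)

    eaf = g.mean(axis=0) / 2.0
    df = pd.DataFrame({
        "variant_id": ids,
        "effect_allele": ea,
        "other_allele": oa,
        "eaf": eaf,
        "beta": beta,
        "se": se,
        "pval": pval,
        "n": cohort.n,
    })[ok]
    return SummaryStatsTable(df, trait_id=trait_name, sample_id=sample_id)


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def _orientation(ref_ea, ref_oa, ea, oa, ref_eaf, eaf) -> int | None:
    """+1 same effect allele, -1 swapped, None unresolvable."""
    if _is_palindromic(ref_ea, ref_oa) or _is_palindromic(ea, oa):
        # labels cannot orient a palindromic variant; fall back to frequency
        if {ea, oa} not in ({ref_ea, ref_oa},
                            {_COMPLEMENT.get(ref_ea, "?"), _COMPLEMENT.get(ref_oa, "?")}):
            return None
        if abs(ref_eaf - 0.5) <= PALINDROME_EAF_MARGIN or abs(eaf - 0.5) <= PALINDROME_EAF_MARGIN:
            return None
        return 1 if (ref_eaf - 0.5) * (eaf - 0.5) > 0 else -1
    if (ea, oa) == (ref_ea, ref_oa):
        return 1
    if (ea, oa) == (ref_oa, ref_ea):
        return -1
    cea, coa = _COMPLEMENT.get(ea), _COMPLEMENT.get(oa)
    if (cea, coa) == (ref_ea, ref_oa):
        return 1
    if (cea, coa) == (ref_oa, ref_ea):
        return -1
    return None


def harmonize_tables(
    exposure_tables: list[SummaryStatsTable],
    outcome_table: SummaryStatsTable,
) -> tuple[list[SummaryStatsTable], SummaryStatsTable]:
    """Align all tables on the first exposure table's effect alleles.

    Returns allele-aligned copies restricted to the variant intersection, in
    the first exposure table's row order.  Variants whose allele pairs cannot
    be reconciled (including unresolvable palindromes) are dropped and logged.
    Idempotent: aligning already-aligned tables changes nothing.
    """
    if len(exposure_tables) < 1:
        raise ValueError("at least one exposure table required")
    ref = exposure_tables[0]
    all_tables = list(exposure_tables) + [outcome_table]

    common = set(ref.variant_ids)
    for t in all_tables[1:]:
        common &= set(t.variant_ids)
    ordered = [v for v in ref.variant_ids if v in common]
    if not ordered:
        raise ValueError("empty variant intersection across tables")

    ref_rows = ref.df.set_index("variant_id")
    aligned: list[SummaryStatsTable] = []
    dropped: set[str] = set()
    frames = []
    for t in all_tables:
        rows = t.df.set_index("variant_id").loc[ordered].reset_index()
        frames.append(rows)
    for v_idx, vid in enumerate(ordered):
        r = ref_rows.loc[vid]
        for rows in frames:
            sign = _orientation(
                r["effect_allele"], r["other_allele"],
                rows.at[v_idx, "effect_allele"], rows.at[v_idx, "other_allele"],
                float(r["eaf"]), float(rows.at[v_idx, "eaf"]),
            )
            if sign is None:
                dropped.add(vid)
                break
            if sign < 0:
                rows.at[v_idx, "beta"] = -rows.at[v_idx, "beta"]
                rows.at[v_idx, "eaf"] = 1.0 - rows.at[v_idx, "eaf"]
            rows.at[v_idx, "effect_allele"] = r["effect_allele"]
            rows.at[v_idx, "other_allele"] = r["other_allele"]
    if dropped:
        logger.warning("harmonize: dropping variants with irreconcilable alleles: %s",
                       sorted(dropped))
    keep = [v for v in ordered if v not in dropped]
    if not keep:
        raise ValueError("no variants left after allele reconciliation")
    out = []
    for t, rows in zip(all_tables, frames):
        kept = rows[rows["variant_id"].isin(keep)]
        out.append(SummaryStatsTable(kept, trait_id=t.trait_id, sample_id=t.sample_id))
    return out[:-1], out[-1]


def harmonize(
    exposure_tables: list[SummaryStatsTable],
    outcome_table: SummaryStatsTable,
) -> HarmonizedDataset:
    """Allele-aligned effect matrices for MR (see :func:`harmonize_tables`)."""
    exp_aligned, out_aligned = harmonize_tables(exposure_tables, outcome_table)
    variant_ids = exp_aligned[0].variant_ids
    bx = np.column_stack([t.df["beta"].to_numpy() for t in exp_aligned])
    se_bx = np.column_stack([t.df["se"].to_numpy() for t in exp_aligned])
    return HarmonizedDataset(
        variant_ids=variant_ids,
        bx=bx,
        se_bx=se_bx,
        by=out_aligned.df["beta"].to_numpy(),
        se_by=out_aligned.df["se"].to_numpy(),
        exposure_ids=[t.trait_id or f"exposure_{j + 1}" for j, t in enumerate(exp_aligned)],
    )


def prune_instruments(
    table: SummaryStatsTable,
    genotypes: pd.DataFrame,
    r2_threshold: float = 0.05,
) -> SummaryStatsTable:
    """Greedy correlation pruning to approximately independent instruments.

    Variants are ranked by ascending p-value; a variant is accepted iff its
    squared Pearson correlation of dosages with every already-accepted variant
    is below ``r2_threshold``.  ``genotypes`` must contain a dosage column per
    variant id in the table (a reference-panel stand-in).  Output preserves
    the input table's row order.
    """
    missing = [v for v in table.variant_ids if v not in genotypes.columns]
    if missing:
        raise KeyError(f"genotype matrix missing dosage columns: {missing}")
    order = table.df.sort_values("pval", kind="mergesort").index
    accepted: list[str] = []
    accepted_dosages: list[np.ndarray] = []
    for idx in order:
        vid = table.df.at[idx, "variant_id"]
        dose = genotypes[vid].to_numpy(dtype=float)
        ok = True
        for kept in accepted_dosages:
            r = np.corrcoef(dose, kept)[0, 1]
            if r * r >= r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(vid)
            accepted_dosages.append(dose)
    keep = table.df["variant_id"].isin(accepted)
    return SummaryStatsTable(table.df[keep], trait_id=table.trait_id,
                             sample_id=table.sample_id)
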