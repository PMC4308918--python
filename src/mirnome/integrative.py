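"""Integrative miRNA:mRNA anti-correlation analysis.

Every (expressed miRNA, expressed mRNA isoform) pair is scored by Spearman
correlation across matched samples.  P-values are BH-corrected within each
miRNA's pair family; candidate repression pairs must be anti-correlated
(rho < 0, q < 0.05).  To discount correlations expected by chance, the rho
distribution is divided into 40 equal-width bins over [-1, 1] and compared
against a null built by recomputing all correlations under 100 random
permutations of the miRNA sample labels; within each bin, only the
(observed - mean null count) pairs with the smallest q survive.  Finally a
pair must carry a predicted binding site from every required predictor.

The pair collection is a pandas DataFrame with columns
(mirna_id, mrna_id, rho, p_value, q_value, bin_index, passed_null,
site_predicted, interaction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust
from .expression import ExpressionMatrix

PAIR_COLUMNS = [
    "mirna_id", "mrna_id", "rho", "p_value", "q_value",
    "bin_index", "passed_null", "site_predicted", "interaction",
]

REGIONS = ("5UTR", "CDS", "3UTR")


@dataclass(frozen=True)
class BindingSite:
    """A predicted miRNA binding site in transcript coordinates
    (0-based half-open), within one of 5'UTR / CDS / 3'UTR."""

    mirna_id: str
    transcript_id: str
    region: str
    start: int
    end: int
    predictor: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("empty binding site")
        if self.region not in REGIONS:
            raise ValueError(f"bad region {self.region!r}")


@dataclass
class NullHistogram:
    bin_edges: np.ndarray  # length n_bins + 1, spanning [-1, 1]
    observed_counts: np.ndarray  # int, per bin
    null_totals: np.ndarray  # int, per bin, summed over permutations
    n_permutations: int
    seed: int | None = None

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def null_counts(self) -> np.ndarray:
        """Mean per-permutation count per bin."""
        return self.null_totals / self.n_permutations


def _rank_standardize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-rank each row, center and scale to unit norm.

    Returns (standardized ranks, validity mask); constant rows (zero rank
    variance) are invalid and zeroed out.
    """
    ranks = stats.rankdata(values, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    valid = norms > 0
    norms[~valid] = 1.0
    return ranks / norms[:, None], valid


def _rho_matrix(mirna_vals: np.ndarray, mrna_vals: np.ndarray) -> np.ndarray:
    """Spearman rho for every miRNA (rows) x mRNA (rows) pair: Pearson
    correlation of mid-ranks.  Constant vectors give NaN."""
    rm, vm = _rank_standardize(mirna_vals)
    rt, vt = _rank_standardize(mrna_vals)
    rho = rm @ rt.T
    rho = np.clip(rho, -1.0, 1.0)
    rho[~vm, :] = np.nan
    rho[:, ~vt] = np.nan
    return rho


def _rho_pvalues(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t approximation with n - 2 df."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    p[np.isnan(rho)] = np.nan
    return np.minimum(p, 1.0)


def _align(mirna: ExpressionMatrix, mrna: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray, list[str]]:
    shared = [s for s in mirna.sample_ids if s in set(mrna.sample_ids)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    return (
        mirna.values[shared].to_numpy(dtype=float),
        mrna.values[shared].to_numpy(dtype=float),
        shared,
    )


def spearman_all_pairs(mirna: ExpressionMatrix, mrna: ExpressionMatrix) -> pd.DataFrame:
    """Spearman rho and p for every miRNA x mRNA pair over shared samples.

    Pairs involving a constant vector get rho = NaN and are excluded from all
    downstream filters.
    """
    mv, tv, shared = _align(mirna, mrna)
    rho = _rho_matrix(mv, tv)
    p = _rho_pvalues(rho, len(shared))
    mirna_ids = np.repeat(mirna.feature_ids, len(mrna.feature_ids))
    mrna_ids = np.tile(mrna.feature_ids, len(mirna.feature_ids))
    return pd.DataFrame(
        {
            "mirna_id": mirna_ids,
            "mrna_id": mrna_ids,
            "rho": rho.ravel(),
            "p_value": p.ravel(),
            "q_value": np.nan,
            "bin_index": -1,
            "passed_null": False,
            "site_predicted": False,
            "interaction": False,
        }
    )


def per_mirna_bh(pairs: pd.DataFrame) -> pd.DataFrame:
    """BH adjustment applied separately within each miRNA's pair family.

    The family size is the number of valid (non-NaN) tested isoforms for that
    miRNA; NaN-rho pairs keep q = NaN.
    """
    q = np.full(len(pairs), np.nan)
    pvals = pairs["p_value"].to_numpy()
    valid = ~np.isnan(pvals)
    codes, _ = pd.factorize(pairs["mirna_id"], sort=False)
    for g in np.unique(codes):
        idx = np.flatnonzero((codes == g) & valid)
        if idx.size:
            q[idx] = bh_adjust(pvals[idx])
    out = pairs.copy()
    out["q_value"] = q
    return out


def anti_correlated(pairs: pd.DataFrame, rho_max: float = 0.0, q_max: float = 0.05) -> pd.DataFrame:
    """Pairs with rho < rho_max and q < q_max (strict)."""
    mask = (pairs["rho"] < rho_max) & (pairs["q_value"] < q_max)
    return pairs[mask.fillna(False)]


def bin_index(rho: np.ndarray, n_bins: int = 40) -> np.ndarray:
    """Right-closed equal-width bins over [-1, 1]; rho = -1 goes to bin 0."""
    rho = np.asarray(rho, dtype=float)
    if np.nanmin(rho) < -1 or np.nanmax(rho) > 1:
        raise ValueError("rho outside [-1, 1]")
    width = 2.0 / n_bins
    idx = np.ceil((rho + 1.0) / width).astype(float) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    out = np.where(np.isnan(rho), -1, idx).astype(int)
    return out


def build_null(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    n_permutations: int = 100,
    n_bins: int = 40,
    seed: int | None = None,
    observed_rho: np.ndarray | None = None,
    permute_mrna: bool = False,
    _identity: bool = False,
) -> NullHistogram:
    """Permutation null of the pairwise rho distribution.

    Each permutation shuffles the miRNA matrix's sample labels (the mRNA
    matrix stays fixed; ``permute_mrna`` flips the target), recomputes all
    pair correlations, and accumulates a histogram on ``n_bins`` equal-width
    bins over [-1, 1].  ``_identity`` is a test hook forcing the identity
    permutation.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    mv, tv, shared = _align(mirna, mrna)
    n = len(shared)
    rng = np.random.default_rng(seed)
    if observed_rho is None:
        observed_rho = _rho_matrix(mv, tv)
    obs = observed_rho[~np.isnan(observed_rho)]
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    observed_counts = np.bincount(bin_index(obs, n_bins), minlength=n_bins)
    null_totals = np.zeros(n_bins, dtype=np.int64)
    for _ in range(n_permutations):
        perm = np.arange(n) if _identity else rng.permutation(n)
        if permute_mrna:
            rho = _rho_matrix(mv, tv[:, perm])
        else:
            rho = _rho_matrix(mv[:, perm], tv)
        flat = rho[~np.isnan(rho)]
        null_totals += np.bincount(bin_index(flat, n_bins), minlength=n_bins)
    return NullHistogram(
        bin_edges=edges,
        observed_counts=observed_counts,
        null_totals=null_totals,
        n_permutations=n_permutations,
        seed=seed,
    )


def bin_rank_filter(pairs: pd.DataFrame, null: NullHistogram) -> pd.DataFrame:
    """Keep, per rho bin, only the count excess over the null.

    Within each bin pairs are sorted by q ascending (ties by p, then by
    (mirna_id, mrna_id)); the top max(0, round(observed - mean null)) get
    ``passed_null=True``.  Rounding is half-up.  Invariant to input order.
    """
    out = pairs.copy()
    rho = out["rho"].to_numpy()
    out["bin_index"] = bin_index(rho, null.n_bins)
    out["passed_null"] = False
    null_counts = null.null_counts
    valid = out[out["bin_index"] >= 0]
    for b, group in valid.groupby("bin_index"):
        n_obs = len(group)
        n_keep = int(np.floor(n_obs - null_counts[b] + 0.5))
        n_keep = max(0, min(n_keep, n_obs))
        if n_keep == 0:
            continue
        ranked = group.sort_values(
            ["q_value", "p_value", "mirna_id", "mrna_id"], kind="mergesort"
        )
        out.loc[ranked.index[:n_keep], "passed_null"] = True
    return out


def _validate_rna(seq: str, name: str) -> str:
    s = seq.upper().replace("U", "T")
    if set(s) - set("ACGT"):
        raise ValueError(f"non-ACGU/ACGT characters in record {name!r}")
    return s


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def seed_match_sites(
    mirna_seqs: dict[str, str],
    transcript_seqs: dict[str, tuple[str, list[tuple[str, int, int]]]],
    predictor: str = "seed-match",
) -> list[BindingSite]:
    """7-mer seed-match stand-in predictor.

    Reports a site wherever the reverse complement of the miRNA seed
    (nucleotides 2-8) occurs in a transcript, provided the 7-mer lies wholly
    within one annotated region (5'UTR/CDS/3'UTR).  ``transcript_seqs`` maps
    transcript id to (sequence, [(region, start, end), ...]) in transcript
    coordinates.
    """
    sites: list[BindingSite] = []
    for mid, mseq in mirna_seqs.items():
        s = _validate_rna(mseq, mid)
        if len(s) < 8:
            raise ValueError(f"miRNA {mid!r} shorter than 8 nt")
        seed = s[1:8]
        probe = seed.translate(_COMPLEMENT)[::-1]  # reverse complement, DNA
        for tid, (tseq, regions) in transcript_seqs.items():
            t = _validate_rna(tseq, tid)
            start = t.find(probe)
            while start != -1:
                end = start + 7
                for region, rstart, rend in regions:
                    if rstart <= start and end <= rend:
                        sites.append(BindingSite(mid, tid, region, start, end, predictor))
                        break
                start = t.find(probe, start + 1)
    return sites


def sites_to_frame(sites: list[BindingSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.mirna_id, s.transcript_id, s.region, s.start, s.end, s.predictor) for s in sites],
        columns=["mirna_id", "transcript_id", "region", "start", "end", "predictor"],
    )


def call_interactions(
    pairs: pd.DataFrame,
    sites_by_predictor: dict[str, pd.DataFrame],
    min_predictors: int | None = None,
    rho_max: float = 0.0,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Combine the expression and binding-site evidence.

    ``site_predicted`` requires at least one site for the (miRNA, transcript)
    pair in every required predictor table (all of them unless
    ``min_predictors`` lowers the bar); ``interaction`` additionally requires
    anti-correlation (rho < 0, q < 0.05 by default) and the permutation-null
    filter.
    """
    if not sites_by_predictor:
        raise ValueError("at least one predictor site table required")
    required = len(sites_by_predictor) if min_predictors is None else min_predictors
    out = pairs.copy()
    key = pd.MultiIndex.from_frame(out[["mirna_id", "mrna_id"]])
    hit_count = np.zeros(len(out), dtype=int)
    for _pred, table in sites_by_predictor.items():
        if len(table) == 0:
            continue
        pred_pairs = pd.MultiIndex.from_frame(
            table[["mirna_id", "transcript_id"]].drop_duplicates()
        )
        hit_count += key.isin(pred_pairs).astype(int)
    out["site_predicted"] = hit_count >= required
    anti = (out["rho"] < rho_max) & (out["q_value"] < q_max)
    out["interaction"] = anti.fillna(False) & out["passed_null"] & out["site_predicted"]
    return out


def integrate(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    sites_by_predictor: dict[str, pd.DataFrame],
    n_permutations: int = 100,
    n_bins: int = 40,
    seed: int | None = None,
    rho_max: float = 0.0,
    q_max: float = 0.05,
) -> tuple[pd.DataFrame, NullHistogram]:
    """Full integrative screen: all-pairs Spearman, per-miRNA BH, permutation
    null with bin-rank filtering, then binding-site intersection."""
    pairs = spearman_all_pairs(mirna, mrna)
    pairs = per_mirna_bh(pairs)
    mv, tv, _ = _align(mirna, mrna)
    observed = _rho_matrix(mv, tv)
    null = build_null(
        mirna, mrna, n_permutations=n_permutations, n_bins=n_bins,
        seed=seed, observed_rho=observed,
    )
    pairs = bin_rank_filter(pairs, null)
    pairs = call_interactions(pairs, sites_by_predictor, rho_max=rho_max, q_max=q_max)
    return pairs, null
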