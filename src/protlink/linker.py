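"""Gaussian naive Bayes genotype inference and odds-product genome matching.

For each (protein, SNP) pair in a reduced pQTL panel, the model stores a
class-conditional Gaussian of the natural-log protein level per genotype
class g in {0, 1, 2}: mean mu_g, SD sigma_g, and the empirical class
frequency as prior P(g).  Given an observed level x,

    P(g | x)  propto  P(g) * N(x; mu_g, sigma_g),

and a candidate genome scores the sum over panel pairs of the log odds of
its dosage at each pair:

    log Odds(g | x) = sum_i [ log P(g_i | x_i) - log(1 - P(g_i | x_i)) ].

Raw products of odds over ~100 pairs under/overflow double precision, so
all arithmetic is in log space, with posteriors clipped to
[1e-12, 1 - 1e-12] before odds.  Sufficient statistics (count, sum, sum
of squares) are stored per class so that incremental training on a second
cohort is exactly equivalent to a single-pass fit on the pooled data.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .containers import GenotypeMatrix, ProteomeMatrix
from .pqtl import PqtlTable

__all__ = [
    "NBModel",
    "LinkResult",
    "fit_nb",
    "update_nb",
    "genotype_posterior",
    "log_odds_genome",
    "rank_genomes",
    "score_matrix",
    "evaluate_matching",
    "top_pct_window",
]

EPS = 1e-12
_LOG2PI = math.log(2.0 * math.pi)


@dataclasses.dataclass
class NBModel:
    """Per-pair, per-genotype-class Gaussian sufficient statistics.

    Arrays are shaped (n_pairs, 3); column g holds the statistics of log
    protein levels among training subjects with dosage g.  Derived
    parameters:

    * ``mu``     — class sample means;
    * ``sigma``  — class sample SDs (n-1 denominator), floored at
      ``sigma_floor_frac`` times the pooled SD; degenerate classes
      (count < ``min_class_n``) fall back to the pooled SD;
    * ``priors`` — empirical class frequencies (a count-0 class has
      prior 0 and is excluded from the posterior's support).
    """

    proteins: np.ndarray
    snps: np.ndarray
    counts: np.ndarray
    sums: np.ndarray
    sumsqs: np.ndarray
    transform: str = "log"
    sigma_floor_frac: float = 1e-6
    min_class_n: int = 2

    def __post_init__(self) -> None:
        n = len(self.proteins)
        for name in ("counts", "sums", "sumsqs"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3)")
            setattr(self, name, arr)
        if (self.counts < 0).any():
            raise ValueError("class counts must be nonnegative")

    @property
    def n_pairs(self) -> int:
        return len(self.proteins)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.proteins, self.snps))

    def pair_index(self, pair: tuple[str, str] | int) -> int:
        if isinstance(pair, (int, np.integer)):
            return int(pair)
        try:
            return self.pairs.index((pair[0], pair[1]))
        except ValueError:
            raise KeyError(f"pair {pair!r} not in model panel") from None

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def mu(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = self.sums / self.counts
        return np.where(self.counts > 0, mu, 0.0)

    @property
    def pooled_sd(self) -> np.ndarray:
        n = self.totals
        s = self.sums.sum(axis=1)
        ss = self.sumsqs.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            var = (ss - s**2 / n) / (n - 1.0)
        return np.sqrt(np.maximum(np.where(n > 1, var, 0.0), 0.0))

    @property
    def sigma(self) -> np.ndarray:
        c = self.counts
        with np.errstate(invalid="ignore", divide="ignore"):
            var = (self.sumsqs - self.sums**2 / c) / (c - 1.0)
        sd = np.sqrt(np.maximum(np.nan_to_num(var, nan=0.0), 0.0))
        pooled = self.pooled_sd[:, None]
        floor = np.maximum(self.sigma_floor_frac * pooled, EPS)
        sd = np.where(c >= self.min_class_n, np.maximum(sd, floor),
                      np.maximum(pooled, floor))
        return np.where(c > 0, sd, 1.0)  # count-0 classes: placeholder, prior 0

    @property
    def priors(self) -> np.ndarray:
        n = self.totals[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            pr = self.counts / n
        return np.where(n > 0, pr, 0.0)

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean (n_pairs, 3) mask of classes with count < min_class_n."""
        return self.counts < self.min_class_n

    # -- serialization -------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "transform": self.transform,
            "sigma_floor_frac": self.sigma_floor_frac,
            "min_class_n": self.min_class_n,
            "proteins": [str(x) for x in self.proteins],
            "snps": [str(x) for x in self.snps],
            "counts": self.counts.tolist(),
            "sums": self.sums.tolist(),
            "sumsqs": self.sumsqs.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NBModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            proteins=np.array(d["proteins"], dtype=object),
            snps=np.array(d["snps"], dtype=object),
            counts=np.array(d["counts"], dtype=float),
            sums=np.array(d["sums"], dtype=float),
            sumsqs=np.array(d["sumsqs"], dtype=float),
            transform=d["transform"],
            sigma_floor_frac=d["sigma_floor_frac"],
            min_class_n=d["min_class_n"],
        )


@dataclasses.dataclass
class LinkResult:
    """One proteome's ranking over candidate genomes.

    ``genome_ids``/``log_odds`` are sorted by non-increasing total log
    odds, ties broken by genome id.  Ranks are 1-based.  The top-1%
    window is ``ceil(0.01 * n_genomes)`` with a minimum of 1.
    """

    proteome_id: str
    genome_ids: np.ndarray
    log_odds: np.ndarray
    rank_of_true: int | None = None
    top1: bool | None = None
    top3: bool | None = None
    top1pct: bool | None = None

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    @property
    def top_genome(self) -> str:
        return self.genome_ids[0]

    def top_posterior(self) -> float:
        """Softmax weight of the top genome over the candidate set."""
        s = self.log_odds - self.log_odds[0]
        return float(1.0 / np.exp(s).sum())


def top_pct_window(n_genomes: int, pct: float = 0.01, mode: str = "ceil") -> int:
    """Size of the top-pct window; ceil by default, never below 1."""
    if mode == "ceil":
        w = math.ceil(pct * n_genomes)
    elif mode == "floor":
        w = math.floor(pct * n_genomes)
    else:
        raise ValueError("mode must be 'ceil' or 'floor'")
    return max(w, 1)


# ---------------------------------------------------------------------
# training
# ---------------------------------------------------------------------

def _panel_arrays(
    p: ProteomeMatrix, g: GenotypeMatrix, proteins: Sequence[str], snps: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    for prot in proteins:
        if prot not in p.proteins:
            raise ValueError(f"panel protein {prot!r} absent from proteome matrix")
    for snp in snps:
        if snp not in g.snp_ids:
            raise ValueError(f"panel SNP {snp!r} absent from genotype matrix")
    shared = p.subjects.intersection(g.subjects)
    X = p.values.loc[shared, list(proteins)].to_numpy(dtype=float)
    D = g.dosages.loc[shared, list(snps)].to_numpy(dtype=float)
    return X, D, shared


def _suffstats(X: np.ndarray, D: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    counts = np.empty((X.shape[1], 3))
    sums = np.empty_like(counts)
    sumsqs = np.empty_like(counts)
    for cls in (0, 1, 2):
        m = (D == cls).astype(float)
        counts[:, cls] = m.sum(axis=0)
        sums[:, cls] = (X * m).sum(axis=0)
        sumsqs[:, cls] = (X**2 * m).sum(axis=0)
    return counts, sums, sumsqs


def fit_nb(p: ProteomeMatrix, g: GenotypeMatrix, panel: PqtlTable, **kwargs) -> NBModel:
    """Fit the class-conditional Gaussians on log protein levels.

    ``panel`` must be a reduced (1:1) pQTL table; per pair and genotype
    class the sufficient statistics are accumulated over training
    subjects present in both matrices (missing dosages contribute to no
    class).
    """
    if p.transform_state != "log":
        raise ValueError("fit_nb requires log-transformed protein values")
    if not panel.reduced:
        raise ValueError("fit_nb requires a reduced 1:1 pQTL panel")
    proteins = panel.records["protein_id"].to_numpy(dtype=object)
    snps = panel.records["snp_id"].to_numpy(dtype=object)
    X, D, _ = _panel_arrays(p, g, proteins, snps)
    counts, sums, sumsqs = _suffstats(X, D)
    return NBModel(proteins, snps, counts, sums, sumsqs, transform="log", **kwargs)


def update_nb(m: NBModel, p2: ProteomeMatrix, g2: GenotypeMatrix) -> NBModel:
    """Incremental training: pool a second cohort's sufficient statistics.

    The result is exactly what a single-pass fit on the concatenated
    cohorts would produce (count/sum/sum-of-squares add).  An empty
    second cohort leaves the model unchanged.
    """
    if p2.transform_state != "log":
        raise ValueError("update_nb requires log-transformed protein values")
    X, D, shared = _panel_arrays(p2, g2, m.proteins, m.snps)
    if len(shared) == 0:
        return dataclasses.replace(
            m, counts=m.counts.copy(), sums=m.sums.copy(), sumsqs=m.sumsqs.copy()
        )
    counts, sums, sumsqs = _suffstats(X, D)
    return dataclasses.replace(
        m,
        counts=m.counts + counts,
        sums=m.sums + sums,
        sumsqs=m.sumsqs + sumsqs,
    )


# ---------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------

def _log_posteriors(m: NBModel, X: np.ndarray) -> np.ndarray:
    """Log P(g | x) for every subject/pair/class; shape (n, n_pairs, 3).

    Computed entirely in log space; classes with prior 0 get -inf and
    are excluded from the normalization.
    """
    mu, sigma, priors = m.mu, m.sigma, m.priors
    with np.errstate(divide="ignore"):
        log_prior = np.log(priors)
    z = (X[:, :, None] - mu[None, :, :]) / sigma[None, :, :]
    log_lik = -0.5 * z**2 - np.log(sigma)[None, :, :] - 0.5 * _LOG2PI
    log_post = log_prior[None, :, :] + log_lik
    norm = logsumexp(log_post, axis=2, keepdims=True)
    return log_post - norm


def genotype_posterior(
    m: NBModel, pair: tuple[str, str] | int, x: float
) -> np.ndarray:
    """Posterior over the three genotype classes given one log level x."""
    if not np.isfinite(x):
        raise ValueError("protein level must be finite")
    i = m.pair_index(pair)
    sub = NBModel(
        m.proteins[i : i + 1], m.snps[i : i + 1],
        m.counts[i : i + 1], m.sums[i : i + 1], m.sumsqs[i : i + 1],
        transform=m.transform, sigma_floor_frac=m.sigma_floor_frac,
        min_class_n=m.min_class_n,
    )
    lp = _log_posteriors(sub, np.array([[float(x)]]))
    return np.exp(lp[0, 0])


def _pair_log_odds(m: NBModel, X: np.ndarray) -> np.ndarray:
    """Per-pair, per-class log odds log(P/(1-P)), clipped; (n, n_pairs, 3)."""
    post = np.exp(_log_posteriors(m, X))
    post = np.clip(post, EPS, 1.0 - EPS)
    return np.log(post) - np.log1p(-post)


def _align_row(values: pd.Series | Mapping, keys: np.ndarray) -> np.ndarray:
    s = pd.Series(values)
    missing = [k for k in keys if k not in s.index]
    if missing:
        raise ValueError(f"row is missing panel entries: {missing[:5]}")
    return s[list(keys)].to_numpy(dtype=float)


def log_odds_genome(m: NBModel, proteome_row, genotype_row) -> float:
    """Total log odds that ``genotype_row`` generated ``proteome_row``.

    ``proteome_row`` maps protein id -> log level; ``genotype_row`` maps
    SNP id -> dosage.  Pairs with a missing dosage are skipped.
    """
    x = _align_row(proteome_row, m.proteins)
    d = _align_row(genotype_row, m.snps)
    lo = _pair_log_odds(m, x[None, :])[0]
    total = 0.0
    for i in range(m.n_pairs):
        if np.isnan(d[i]):
            continue
        total += lo[i, int(d[i])]
    return float(total)


def score_matrix(
    m: NBModel, proteomes: ProteomeMatrix, genomes: GenotypeMatrix
) -> pd.DataFrame:
    """Total log odds for every (proteome, genome) combination.

    Rows are proteome subjects, columns genome subjects.  Missing
    dosages contribute nothing to a genome's score.
    """
    if proteomes.transform_state != "log":
        raise ValueError("matching requires log-transformed protein values")
    X = proteomes.values.loc[:, list(m.proteins)].to_numpy(dtype=float)
    G = genomes.dosages.loc[:, list(m.snps)].to_numpy(dtype=float)
    lo = _pair_log_odds(m, X)  # (nP, N, 3)
    scores = np.zeros((X.shape[0], G.shape[0]))
    for cls in (0, 1, 2):
        member = (G == cls).astype(float).T  # (N, nG)
        scores += lo[:, :, cls] @ member
    return pd.DataFrame(scores, index=proteomes.subjects, columns=genomes.subjects)


def _ranked(scores: np.ndarray, genome_ids: np.ndarray) -> np.ndarray:
    """Indices sorting scores descending, ties broken by genome id."""
    return np.lexsort((genome_ids, -scores))


def rank_genomes(
    m: NBModel,
    proteome_row,
    genomes: GenotypeMatrix,
    proteome_id: str = "query",
    true_genome: str | None = None,
    pct_mode: str = "ceil",
) -> LinkResult:
    """Score every candidate genome for one proteome and rank them."""
    if genomes.n_subjects == 0:
        raise ValueError("empty genome set")
    x = _align_row(proteome_row, m.proteins)
    pm = ProteomeMatrix(
        pd.DataFrame([x], index=[proteome_id], columns=list(m.proteins)),
        transform_state="log",
    )
    s = score_matrix(m, pm, genomes).iloc[0]
    return _result_from_scores(
        proteome_id, s.to_numpy(), np.asarray(s.index, dtype=object),
        true_genome, pct_mode,
    )


def _result_from_scores(
    proteome_id: str,
    scores: np.ndarray,
    genome_ids: np.ndarray,
    true_genome: str | None,
    pct_mode: str = "ceil",
) -> LinkResult:
    order = _ranked(scores, genome_ids)
    ranked_ids = genome_ids[order]
    ranked_scores = scores[order]
    res = LinkResult(proteome_id, ranked_ids, ranked_scores)
    if true_genome is not None:
        pos = np.nonzero(ranked_ids == true_genome)[0]
        if pos.size == 0:
            raise ValueError(f"true genome {true_genome!r} not in candidate set")
        rank = int(pos[0]) + 1
        res.rank_of_true = rank
        res.top1 = rank <= 1
        res.top3 = rank <= 3
        res.top1pct = rank <= top_pct_window(len(genome_ids), mode=pct_mode)
    return res


def evaluate_matching(
    m: NBModel,
    proteomes: ProteomeMatrix,
    genomes: GenotypeMatrix,
    truth: Mapping[str, str],
    populations: Mapping[str, str] | None = None,
    pct_mode: str = "ceil",
) -> dict:
    """Top-1 / top-3 / top-1% matching accuracy over a proteome set.

    ``truth`` maps each proteome subject to its genome id (which must be
    in the candidate set).  Optionally stratifies by a population label
    per proteome subject.
    """
    for pid in proteomes.subjects:
        if pid not in truth:
            raise ValueError(f"proteome {pid!r} has no truth mapping")
        if truth[pid] not in genomes.subjects:
            raise ValueError(f"true genome {truth[pid]!r} not in genome set")
    S = score_matrix(m, proteomes, genomes)
    genome_ids = np.asarray(S.columns, dtype=object)
    window = top_pct_window(len(genome_ids), mode=pct_mode)
    ranks = {}
    for pid, row in zip(S.index, S.to_numpy()):
        order = _ranked(row, genome_ids)
        ranks[pid] = int(np.nonzero(genome_ids[order] == truth[pid])[0][0]) + 1
    rank_s = pd.Series(ranks, name="rank_of_true")

    def _summ(sub: pd.Series) -> dict:
        return {
            "n": int(len(sub)),
            "top1": float((sub <= 1).mean()),
            "top3": float((sub <= 3).mean()),
            "top1pct": float((sub <= window).mean()),
        }

    out = _summ(rank_s)
    out["window"] = window
    out["ranks"] = rank_s
    if populations is not None:
        pops = pd.Series({pid: populations[pid] for pid in rank_s.index})
        out["by_population"] = {
            pop: _summ(rank_s[pops == pop]) for pop in sorted(pops.unique())
        }
    return out
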