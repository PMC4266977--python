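"""Stemward-slippage tests: synapomorphic ranks vs decay ranks.

Stemward slippage is the bias by which decay preferentially destroys
synapomorphies, so badly decayed fossils resolve too close to the stem of
their clade.  The test battery correlates each character's *decay rank*
(1 = most decay-prone) with its *synapomorphic rank* (1 = apomorphy of the
least-inclusive clade containing the focal terminal, increasing root-ward)
using Spearman's rank correlation, once per phylogenetic hypothesis and per
homology treatment of contested characters.  Under this pairing, slippage in
the classic (chordate-like) direction appears as a *positive* correlation;
decay-prone symplesiomorphies with decay-resistant apomorphies give a
negative one.

P-values are two-sided by default: exact permutation enumeration for small
n, seeded Monte Carlo permutation or the t approximation otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.stats import rankdata

from .datamodel import PhyloHypothesis, ValidationError
from .scoring import DecayRankTable

__all__ = [
    "SynapomorphicRanking",
    "SlippageTestResult",
    "synapomorphic_rank",
    "filter_informative",
    "spearman",
    "run_test_battery",
    "compare_taxa_ranks",
    "holm_adjust",
]

EXACT_N_MAX = 8
DEFAULT_N_PERM = 100_000
DEFAULT_SEED = 1_234_567


@dataclass(frozen=True)
class SynapomorphicRanking:
    """Midranks of characters by the inclusiveness of the clade they diagnose."""

    hypothesis_id: str
    treatment: str  # "homology" or "homoplasy"
    ranks: dict[str, float]
    depths: dict[str, int]
    path_depth_range: tuple[int, int]  # (tipmost, rootmost) assignable depth


@dataclass(frozen=True)
class SlippageTestResult:
    hypothesis_id: str
    treatment: str
    n_characters: int
    r_s: float
    p_value: float
    p_method: str
    filtered: bool

    def __post_init__(self) -> None:
        if not -1 - 1e-12 <= self.r_s <= 1 + 1e-12:
            raise ValidationError(f"r_s out of range: {self.r_s}")
        if not 0 < self.p_value <= 1:
            raise ValidationError(f"p out of range: {self.p_value}")


def synapomorphic_rank(
    hypothesis: PhyloHypothesis, treatment: str = "homology"
) -> SynapomorphicRanking:
    """Rank characters by the depth of their assigned node on the focal path.

    Depth is the number of edges from the assigned node down to the focal
    terminal; characters sharing a node share a midrank.  Under the
    ``homoplasy`` treatment contested characters use their alternative node,
    under ``homology`` their primary node.
    """
    if treatment not in ("homology", "homoplasy"):
        raise ValidationError(f"unknown treatment {treatment!r}")
    depths_by_node = hypothesis.path_depths()
    char_depth: dict[str, int] = {}
    for char, node in hypothesis.assignments.items():
        if treatment == "homoplasy" and char in hypothesis.contested:
            node = hypothesis.contested[char]
        char_depth[char] = depths_by_node[node]
    chars = sorted(char_depth)
    depth_vec = np.array([char_depth[c] for c in chars], dtype=float)
    ranks = rankdata(depth_vec, method="average")
    all_depths = list(depths_by_node.values())
    return SynapomorphicRanking(
        hypothesis_id=hypothesis.hypothesis_id,
        treatment=treatment,
        ranks={c: float(r) for c, r in zip(chars, ranks)},
        depths=char_depth,
        path_depth_range=(min(all_depths), max(all_depths)),
    )


def filter_informative(
    ranking: SynapomorphicRanking, decay_ranks: DecayRankTable
) -> tuple[SynapomorphicRanking, DecayRankTable]:
    """Drop characters uninformative for placing fossils within the group.

    Characters assigned to the least-inclusive node of the focal path
    (apomorphies of the focal taxon itself) and to the most-inclusive,
    root-adjacent node (symplesiomorphies of the whole group) cannot move a
    fossil's position within the path, so both extremes are removed and both
    tables are re-ranked over the survivors.
    """
    lo, hi = ranking.path_depth_range
    keep = [
        c
        for c in ranking.depths
        if lo < ranking.depths[c] < hi and c in decay_ranks.ranks
    ]
    if len(keep) < 3:
        raise ValidationError(
            f"only {len(keep)} informative characters remain; need at least 3"
        )
    keep = sorted(keep)
    depth_vec = np.array([ranking.depths[c] for c in keep], dtype=float)
    new_syn = rankdata(depth_vec, method="average")
    decay_vec = np.array([decay_ranks.ranks[c] for c in keep], dtype=float)
    new_decay = rankdata(decay_vec, method="average")
    filtered_ranking = SynapomorphicRanking(
        hypothesis_id=ranking.hypothesis_id,
        treatment=ranking.treatment,
        ranks={c: float(r) for c, r in zip(keep, new_syn)},
        depths={c: ranking.depths[c] for c in keep},
        path_depth_range=ranking.path_depth_range,
    )
    filtered_decay = DecayRankTable(
        ranks={c: float(r) for c, r in zip(keep, new_decay)},
        tie_groups={c: decay_ranks.tie_groups.get(c, 0) for c in keep},
    )
    return filtered_ranking, filtered_decay


def _perm_corr(rx: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Pearson correlation of centred rx against each row of permuted ranks."""
    rxc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc**2).sum() * (pc**2).sum(axis=1))
    return pc @ rxc / denom


def spearman(
    x,
    y,
    p_method: str = "auto",
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = DEFAULT_SEED,
) -> tuple[float, float, str]:
    """Spearman rank correlation with a two-sided p-value.

    Midranks are applied internally, so raw values, ranks, or tied ranks are
    all acceptable input.  ``p_method``:

    - ``exact_permutation`` — full enumeration of all n! pairings (n <= 8);
    - ``monte_carlo`` — seeded random permutations, p = (1+hits)/(1+B);
    - ``t_approx`` — t = r_s * sqrt((n-2)/(1-r_s^2)) on n-2 df;
    - ``auto`` — exact for n <= 8, Monte Carlo otherwise.

    Returns ``(r_s, p, method_used)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValidationError(f"need n >= 3 observations, got {n}")
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValidationError("constant ranks: correlation undefined")
    rxc, ryc = rx - rx.mean(), ry - ry.mean()
    r = float(rxc @ ryc / math.sqrt((rxc**2).sum() * (ryc**2).sum()))

    if p_method == "auto":
        p_method = "exact_permutation" if n <= EXACT_N_MAX else "monte_carlo"

    tol = 1e-12
    if p_method == "exact_permutation":
        if n > EXACT_N_MAX:
            raise ValidationError(
                f"exact enumeration limited to n <= {EXACT_N_MAX}, got {n}"
            )
        perms = np.array(list(itertools.permutations(ry)), dtype=float)
        r_all = _perm_corr(rx, perms)
        p = float((np.abs(r_all) >= abs(r) - tol).mean())
    elif p_method == "monte_carlo":
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(ry, (n_perm, 1)), axis=1)
        r_all = _perm_corr(rx, perms)
        hits = int((np.abs(r_all) >= abs(r) - tol).sum())
        p = (1 + hits) / (1 + n_perm)
    elif p_method == "t_approx":
        if abs(r) >= 1:
            p = 2.0 / math.factorial(n) if n <= 20 else np.finfo(float).tiny
        else:
            t = r * math.sqrt((n - 2) / (1 - r * r))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
    else:
        raise ValidationError(f"unknown p_method {p_method!r}")
    return r, min(max(p, np.finfo(float).tiny), 1.0), p_method


def run_test_battery(
    decay_ranks: DecayRankTable,
    hypotheses: list[PhyloHypothesis],
    filtered: bool = False,
    p_method: str = "auto",
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = DEFAULT_SEED,
    holm: bool = False,
) -> list[SlippageTestResult]:
    """One Spearman test per hypothesis x homology treatment.

    A hypothesis with contested characters contributes two tests (homology
    and homoplasy treatments), one otherwise; four hypotheses with contested
    characters yield the classic battery of 8 tests.  With ``filtered=True``
    the uninformative extremes are removed first.  Results are deterministic
    for a fixed seed and invariant to hypothesis or character order.
    """
    if not hypotheses:
        raise ValidationError("need at least one hypothesis")
    results = []
    for hyp in sorted(hypotheses, key=lambda h: h.hypothesis_id):
        treatments = ["homology", "homoplasy"] if hyp.contested else ["homology"]
        for treatment in treatments:
            ranking = synapomorphic_rank(hyp, treatment)
            if filtered:
                ranking, dranks = filter_informative(ranking, decay_ranks)
            else:
                dranks = decay_ranks
            chars = sorted(set(ranking.ranks) & set(dranks.ranks))
            if len(chars) < 3:
                raise ValidationError(
                    f"hypothesis {hyp.hypothesis_id!r}: only {len(chars)} shared "
                    "characters between decay and synapomorphic rankings"
                )
            x = np.array([dranks.ranks[c] for c in chars])
            y = np.array([ranking.ranks[c] for c in chars])
            r, p, method = spearman(x, y, p_method=p_method, n_perm=n_perm, seed=seed)
            results.append(
                SlippageTestResult(
                    hypothesis_id=hyp.hypothesis_id,
                    treatment=treatment,
                    n_characters=len(chars),
                    r_s=r,
                    p_value=p,
                    p_method=method,
                    filtered=filtered,
                )
            )
    if holm:
        adj = holm_adjust([r.p_value for r in results])
        results = [
            SlippageTestResult(
                r.hypothesis_id, r.treatment, r.n_characters, r.r_s, pa,
                r.p_method, r.filtered,
            )
            for r, pa in zip(results, adj)
        ]
    return results


def compare_taxa_ranks(
    ranks_a: DecayRankTable,
    ranks_b: DecayRankTable,
    p_method: str = "auto",
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = DEFAULT_SEED,
) -> SlippageTestResult:
    """Spearman correlation of two taxa's decay ranks over shared characters.

    A high positive correlation means the two taxa lose characters in the
    same order, even if their absolute decay rates differ.  Ranks are
    recomputed within the shared character set before correlating.
    """
    shared = sorted(set(ranks_a.ranks) & set(ranks_b.ranks))
    if not shared:
        raise ValidationError("no shared characters between the two rank tables")
    if len(shared) < 3:
        raise ValidationError(f"only {len(shared)} shared characters; need >= 3")
    a = rankdata([ranks_a.ranks[c] for c in shared], method="average")
    b = rankdata([ranks_b.ranks[c] for c in shared], method="average")
    r, p, method = spearman(a, b, p_method=p_method, n_perm=n_perm, seed=seed)
    return SlippageTestResult(
        hypothesis_id="cross-taxon",
        treatment="decay-vs-decay",
        n_characters=len(shared),
        r_s=r,
        p_value=p,
        p_method=method,
        filtered=False,
    )


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjustment (family-wise error control)."""
    m = len(p_values)
    order = np.argsort(p_values)
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p_values[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()
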