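"""Signed-rank screening of structural indices against the network background.

Each miRNA's NOG (and, separately, TFP) is compared with the distribution of
that index over the other miRNAs of the condition network: a one-sample
Wilcoxon signed-rank test on the differences candidate - background_i with
alternative "greater".  A miRNA is called a candidate biomarker when both
indices are significantly large (both raw p < alpha, no cross-miRNA
correction).  Because the test depends only on the candidate value and the
background multiset, miRNAs sharing an index value receive identical p-values.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .datasets import read_id_list
from .network import MiRNAStructuralScore, normalize_mirna_id, round_tfp, strip_arm

# Exact enumeration of the signed-rank distribution is used up to this size
# (tie-free, classic zero handling); beyond it the normal approximation with
# tie and continuity corrections takes over.
EXACT_N_MAX = 12


@dataclass(frozen=True)
class ScreenConfig:
    alpha: float = 0.05
    zero_policy: str = "wilcoxon"  # drop zero differences; "pratt" keeps them in ranking
    include_self: bool = False  # include the candidate in its own background

    def __post_init__(self) -> None:
        if not 0 < self.alpha:
            raise ValueError("alpha must be positive")
        if self.zero_policy not in ("wilcoxon", "pratt"):
            raise ValueError(f"unknown zero_policy: {self.zero_policy!r}")


@dataclass
class BiomarkerCall:
    mirna_id: str
    nog: int
    tfp: float
    p_nog: float
    p_tfp: float
    targets: frozenset[str]
    is_candidate: bool
    is_known: bool = False


def _exact_signed_rank_sf(ranks: np.ndarray, w_obs: float) -> float:
    """P(W+ >= w_obs) over all 2^n equiprobable sign assignments.

    Computed by convolving the generating polynomial prod(1 + x^r) over the
    (integer, tie-free) ranks 1..n.
    """
    total = int(ranks.sum())
    counts = np.zeros(total + 1, dtype=np.int64)
    counts[0] = 1
    for r in ranks.astype(int):
        counts[r:] = counts[r:] + counts[:-r]
    w_ceil = math.ceil(w_obs - 1e-9)
    tail = counts[w_ceil:].sum()
    return float(tail) / float(2 ** len(ranks))


def wilcoxon_signed_rank_p(
    background: Sequence[float] | np.ndarray,
    candidate_value: float,
    alternative: str = "greater",
    zero_policy: str = "wilcoxon",
    method: str = "auto",
) -> float:
    """One-sample signed-rank p for "candidate exceeds the background".

    The differences d_i = candidate_value - background_i are ranked by |d|
    with average ranks for ties; W+ is the sum of positively signed ranks.
    ``method`` selects the exact 2^n enumeration ("exact", tie-free only),
    the normal approximation with tie and continuity corrections ("normal"),
    or the size-based default ("auto": exact when n <= 12 and tie-free).
    Zero differences are dropped under the classic convention
    (``zero_policy="wilcoxon"``); under "pratt" they enter the ranking but
    not W+.  All differences zero yields p = 1 with a degeneracy warning.
    """
    if alternative != "greater":
        raise ValueError("only the 'greater' alternative is supported")
    bg = np.asarray(background, dtype=float)
    if bg.size == 0:
        raise ValueError("background is empty")
    d = candidate_value - bg
    n_zero = int((d == 0).sum())
    if zero_policy == "wilcoxon":
        d = d[d != 0]
        n_zero_ranked = 0
    else:
        n_zero_ranked = n_zero
    if d.size == 0 or (zero_policy == "pratt" and (d != 0).sum() == 0):
        warnings.warn("all differences are zero: signed-rank test is degenerate")
        return 1.0
    abs_d = np.abs(d)
    ranks = stats.rankdata(abs_d, method="average")
    if zero_policy == "pratt":
        # zeros carry the smallest ranks but contribute to neither W+ nor W-
        w_plus = float(ranks[d > 0].sum())
        nonzero = d != 0
    else:
        w_plus = float(ranks[d > 0].sum())
        nonzero = np.ones(d.size, dtype=bool)
    n = int(d.size)
    tie_free = np.unique(abs_d[nonzero]).size == nonzero.sum() and n_zero_ranked == 0
    if method == "exact" or (method == "auto" and n <= EXACT_N_MAX and tie_free):
        if not tie_free:
            raise ValueError("exact enumeration requires tie-free differences")
        return _exact_signed_rank_sf(np.sort(ranks), w_plus)
    # normal approximation
    if zero_policy == "pratt":
        t0 = n_zero_ranked
        mu = (n * (n + 1) - t0 * (t0 + 1)) / 4.0
        var = (n * (n + 1) * (2 * n + 1) - t0 * (t0 + 1) * (2 * t0 + 1)) / 24.0
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(abs_d[nonzero], return_counts=True)
    var -= float(((tie_counts**3 - tie_counts).sum())) / 48.0
    if var <= 0:
        warnings.warn("degenerate signed-rank variance; returning p = 1")
        return 1.0
    z = (w_plus - mu - 0.5) / math.sqrt(var)
    return float(stats.norm.sf(z))


def screen_biomarkers(
    scores: Sequence[MiRNAStructuralScore],
    config: ScreenConfig = ScreenConfig(),
) -> list[BiomarkerCall]:
    """Call candidate biomarkers: both NOG and TFP significantly large.

    The background for each miRNA is the index over all other miRNAs
    (leave-one-out by default).  ``alpha >= 1`` bypasses the screen entirely:
    every scored miRNA is carried forward as a candidate, for workflows whose
    input network already contains only pre-screened miRNAs.  Output order is
    stable on the input order of ``scores``.
    """
    if len(scores) < 6:
        raise ValueError("need at least six scored miRNAs to form a background")
    nogs = np.array([s.nog for s in scores], dtype=float)
    tfps = np.array([s.tfp for s in scores], dtype=float)
    calls = []
    for i, s in enumerate(scores):
        if config.include_self:
            bg_nog, bg_tfp = nogs, tfps
        else:
            bg_nog = np.delete(nogs, i)
            bg_tfp = np.delete(tfps, i)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_nog = wilcoxon_signed_rank_p(bg_nog, s.nog, zero_policy=config.zero_policy)
            p_tfp = wilcoxon_signed_rank_p(bg_tfp, s.tfp, zero_policy=config.zero_policy)
        s.p_nog, s.p_tfp = p_nog, p_tfp
        is_candidate = (
            True
            if config.alpha >= 1
            else (p_nog < config.alpha and p_tfp < config.alpha)
        )
        calls.append(
            BiomarkerCall(
                mirna_id=s.mirna_id,
                nog=s.nog,
                tfp=s.tfp,
                p_nog=p_nog,
                p_tfp=p_tfp,
                targets=s.targets,
                is_candidate=is_candidate,
            )
        )
    return calls


def annotate_known(
    calls: Iterable[BiomarkerCall],
    known_file: str | Path | None,
    arm_insensitive: bool = True,
) -> list[BiomarkerCall]:
    """Flag calls whose id appears in a curated known-biomarker list.

    With ``arm_insensitive`` (default) the -3p/-5p arm suffix is ignored on
    both sides, so a literature entry "miR-145" (or the other arm's official
    id) matches the candidate "miR-145-5p".  A missing file leaves every call
    unknown.
    """
    calls = list(calls)
    known: set[str] = set()
    if known_file is not None and Path(known_file).exists():
        for raw in read_id_list(known_file):
            m = normalize_mirna_id(raw)
            known.add(strip_arm(m).lower() if arm_insensitive else m.lower())
    for c in calls:
        key = (
            strip_arm(c.mirna_id).lower() if arm_insensitive else c.mirna_id.lower()
        )
        c.is_known = key in known
    return calls


def write_calls(calls: Iterable[BiomarkerCall], path: str | Path) -> None:
    """Candidate table TSV mirroring the score layout plus the known flag."""
    with open(path, "w") as fh:
        fh.write("mirna_id\tnog\tp_nog\ttfp\tp_tfp\ttargets\tis_candidate\tis_known\n")
        for c in calls:
            fh.write(
                f"{c.mirna_id}\t{c.nog}\t{c.p_nog:.6g}\t{round_tfp(c.tfp):.2f}"
                f"\t{c.p_tfp:.6g}\t{';'.join(sorted(c.targets))}"
                f"\t{int(c.is_candidate)}\t{int(c.is_known)}\n"
            )
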