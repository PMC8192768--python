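"""Per-position mutation-enrichment statistics between tox and nox groups.

For every scheme position the number of mutated (M) and non-mutated (NM)
sequences is tabulated per phenotype group, the sample odds ratio

    OR_i = (tox_M / tox_NM) / (nox_M / nox_NM)

is computed together with a two-sided Fisher exact p-value and a 95%
confidence interval, and positions are partitioned into tox-enriched
(p < alpha, OR > 1), nox-enriched (p < alpha, OR < 1) and non-significant.
A two-sample t-test compares the per-sequence somatic-mutation count
distributions (PDSM) of two groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import MISSING
from .germline_align import SMutEncoding

logger = logging.getLogger(__name__)

_Z975 = sps.norm.ppf(0.975)


@dataclass(frozen=True)
class PositionStats:
    position: int
    tox_M: int
    tox_NM: int
    nox_M: int
    nox_NM: int
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float


def count_positions(encodings: Sequence[SMutEncoding],
                    labels: Mapping[str, str],
                    universe: Iterable[int] | None = None,
                    missing_as_unmutated: bool = True) -> pd.DataFrame:
    """Tabulate mutated/unmutated counts per position for tox vs nox.

    By default a position the LC does not cover counts as non-mutated (a
    truncated sequence carries no somatic mutation there); with
    ``missing_as_unmutated=False`` uncovered positions drop out of that
    position's table entirely.
    """
    groups = {"tox": [], "nox": []}
    for enc in encodings:
        lab = labels[enc.sequence_id]
        if lab in groups:
            groups[lab].append(enc)
    if not groups["tox"] or not groups["nox"]:
        raise ValueError("both a tox and a nox group are required")
    if universe is None:
        universe = sorted({p for enc in encodings for p in enc.token_by_position})
    rows = []
    for pos in universe:
        counts = {}
        for name, encs in groups.items():
            m = nm = 0
            for enc in encs:
                tok = enc.token_by_position.get(pos, MISSING)
                if tok == MISSING:
                    if missing_as_unmutated:
                        nm += 1
                elif tok == "X":
                    nm += 1
                else:
                    m += 1
            counts[name] = (m, nm)
        rows.append({"position": pos,
                     "tox_M": counts["tox"][0], "tox_NM": counts["tox"][1],
                     "nox_M": counts["nox"][0], "nox_NM": counts["nox"][1]})
    logger.info("counted %d positions over %d tox / %d nox sequences",
                len(rows), len(groups["tox"]), len(groups["nox"]))
    return pd.DataFrame(rows)


def fisher_or(tox_M: int, tox_NM: int, nox_M: int, nox_NM: int
              ) -> tuple[float, tuple[float, float], float]:
    """Sample odds ratio, 95% CI and two-sided Fisher exact p for one position.

    The odds ratio is the literal cross-product ratio (no continuity
    correction); zero cells yield 0, inf or nan.  The confidence interval
    uses the Haldane-Anscombe 0.5-corrected Woolf logit interval so it
    stays finite.  The p-value sums hypergeometric point probabilities not
    exceeding the observed table's, matching R's ``fisher.test``.
    """
    a, b, c, d = tox_M, tox_NM, nox_M, nox_NM
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = math.inf
    else:
        odds = math.nan
    ah, bh, ch, dh = (a + 0.5, b + 0.5, c + 0.5, d + 0.5)
    log_or = math.log(ah * dh / (bh * ch))
    se = math.sqrt(1 / ah + 1 / bh + 1 / ch + 1 / dh)
    ci = (math.exp(log_or - _Z975 * se), math.exp(log_or + _Z975 * se))
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, ci, float(p)


def position_stats(counts: pd.DataFrame) -> list[PositionStats]:
    """Attach odds ratio, CI and Fisher p to a per-position count table."""
    out = []
    for row in counts.itertuples(index=False):
        odds, ci, p = fisher_or(row.tox_M, row.tox_NM, row.nox_M, row.nox_NM)
        out.append(PositionStats(int(row.position), int(row.tox_M), int(row.tox_NM),
                                 int(row.nox_M), int(row.nox_NM), odds, ci, p))
    return out


def stats_frame(stats: Sequence[PositionStats]) -> pd.DataFrame:
    return pd.DataFrame([{
        "position": s.position, "tox_M": s.tox_M, "tox_NM": s.tox_NM,
        "nox_M": s.nox_M, "nox_NM": s.nox_NM, "odds_ratio": s.odds_ratio,
        "ci_low": s.ci95[0], "ci_high": s.ci95[1], "p_value": s.p_value,
    } for s in stats])


def classify_positions(stats: Sequence[PositionStats], alpha: float = 0.05
                       ) -> dict[str, set[int]]:
    """Tri-partition positions by significance and direction of enrichment."""
    enriched_tox, enriched_nox, nonsig = set(), set(), set()
    for s in stats:
        if s.p_value < alpha and s.odds_ratio > 1:
            enriched_tox.add(s.position)
        elif s.p_value < alpha and s.odds_ratio < 1:
            enriched_nox.add(s.position)
        else:
            nonsig.add(s.position)
    return {"enriched_in_tox": enriched_tox,
            "enriched_in_nox": enriched_nox,
            "nonsignificant": nonsig}


def pdsm_compare(sm_counts_a: Sequence[int], sm_counts_b: Sequence[int]
                 ) -> tuple[float, float]:
    """Welch two-sample t-test on per-sequence somatic-mutation counts."""
    a = np.asarray(sm_counts_a, dtype=float)
    b = np.asarray(sm_counts_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 sequences")
    if a.std() == 0 and b.std() == 0:
        # degenerate: both groups constant
        return (0.0, 1.0) if a.mean() == b.mean() else (math.inf * np.sign(a.mean() - b.mean()), 0.0)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
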