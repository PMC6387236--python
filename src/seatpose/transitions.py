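"""Posture-transition statistics for paired categorical data.

Between consecutive analysis intervals every participant contributes one
paired observation (posture before, posture after). The analysis:

* square 8x8 contingency (transition) tables per interval pair;
* pairwise McNemar tests on the discordant counts ``b`` (moves i->j) and
  ``c`` (moves j->i), using the continuity-corrected chi-square statistic
  ``(|b - c| - 1)^2 / (b + c)`` on 1 degree of freedom. The corrected
  difference is deliberately NOT clamped at zero, so ``b == c`` gives a
  statistic of ``1/(b + c)`` — the convention that reproduces the
  reference cohort's published p-values. A pair is eligible for testing
  only when both discordant counts are positive;
* Bowker's global test of table symmetry: the sum of UNcorrected pairwise
  statistics over pairs with a nonzero discordant sum, on that many
  degrees of freedom;
* per-interval posture distributions and the monotonicity classification
  of each participant's three-interval posture triple.

The whole analysis is wrapped statsmodels-style: build a
:class:`PostureTransitionModel` from classified results (or directly from
two transition tables), call :meth:`~PostureTransitionModel.fit`, and
read estimates, tests and the ``summary()`` off the returned
:class:`PostureTransitionResults`.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from decimal import ROUND_HALF_DOWN, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ParticipantResult, ParticipantStatus
from .postures import PostureLabel, RECOGNIZED

__all__ = [
    "TransitionTable",
    "McNemarResult",
    "BowkerResult",
    "TripleClass",
    "build_transition_table",
    "mcnemar_cc",
    "eligible_pairs",
    "bowker",
    "interval_distribution",
    "classify_triple",
    "format_pvalue",
    "significance_band",
    "transition_report",
    "PostureTransitionModel",
    "PostureTransitionResults",
]

_K = len(RECOGNIZED)
_INDEX = {label: i for i, label in enumerate(RECOGNIZED)}


# ---------------------------------------------------------------------------
# core statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransitionTable:
    """Square posture-transition counts between two intervals."""

    counts: np.ndarray
    from_interval: str = "TI1"
    to_interval: str = "TI2"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (_K, _K):
            raise ValueError(f"transition table must be {_K}x{_K}")
        if np.any(counts < 0):
            raise ValueError("transition counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def cell(self, row: PostureLabel, col: PostureLabel) -> int:
        return int(self.counts[_INDEX[row], _INDEX[col]])

    def discordant(self, pair: tuple[PostureLabel, PostureLabel]) -> tuple[int, int]:
        """(b, c): counts moving i->j and j->i for an unordered pair."""
        i, j = (_INDEX[p] for p in pair)
        return int(self.counts[i, j]), int(self.counts[j, i])

    def to_frame(self) -> pd.DataFrame:
        labels = [p.value for p in RECOGNIZED]
        return pd.DataFrame(self.counts, index=labels, columns=labels)

    def row_margin(self) -> dict[PostureLabel, int]:
        return {p: int(s) for p, s in zip(RECOGNIZED, self.counts.sum(axis=1))}

    def col_margin(self) -> dict[PostureLabel, int]:
        return {p: int(s) for p, s in zip(RECOGNIZED, self.counts.sum(axis=0))}


def build_transition_table(
    results: Sequence[ParticipantResult],
    from_interval: str = "TI1",
    to_interval: str = "TI2",
) -> TransitionTable:
    """Count participants moving between postures across two intervals."""
    counts = np.zeros((_K, _K), dtype=int)
    attr = {"TI1": "ti1", "TI2": "ti2", "TI3": "ti3"}
    for key in (from_interval, to_interval):
        if key not in attr:
            raise ValueError(f"unknown interval {key!r}")
    for r in results:
        if r.status is not ParticipantStatus.OK:
            raise ValueError(
                f"participant {r.participant} has status {r.status.value}; "
                "exclude non-OK participants before building tables"
            )
        i = _INDEX[getattr(r, attr[from_interval])]
        j = _INDEX[getattr(r, attr[to_interval])]
        counts[i, j] += 1
    return TransitionTable(counts, from_interval, to_interval)


@dataclass(frozen=True)
class McNemarResult:
    """Continuity-corrected McNemar test for one posture pair (df = 1)."""

    pair: tuple[PostureLabel, PostureLabel]
    b: int
    c: int
    statistic: float
    pvalue: float

    @property
    def pair_name(self) -> str:
        return f"{self.pair[0].value}-{self.pair[1].value}"


def mcnemar_cc(
    b: int,
    c: int,
    pair: tuple[PostureLabel, PostureLabel] = (PostureLabel.P1, PostureLabel.P2),
    variant: str = "cc",
) -> McNemarResult:
    """McNemar test on discordant counts ``b`` and ``c``.

    ``variant='cc'`` (default): continuity-corrected chi-square
    ``(|b - c| - 1)^2 / (b + c)``, no clamping, so equal counts give a
    positive statistic ``1/(b + c)``. ``'uncorrected'``: ``(b - c)^2 /
    (b + c)``. ``'exact'``: two-sided binomial test of b successes in
    b + c trials at p = 1/2.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        raise ValueError("no discordant pairs: b + c must be positive")
    if variant == "cc":
        statistic = (abs(b - c) - 1) ** 2 / n
        pvalue = float(stats.chi2.sf(statistic, df=1))
    elif variant == "uncorrected":
        statistic = (b - c) ** 2 / n
        pvalue = float(stats.chi2.sf(statistic, df=1))
    elif variant == "exact":
        res = stats.binomtest(b, n, p=0.5)
        statistic, pvalue = float(min(b, c)), float(res.pvalue)
    else:
        raise ValueError(f"unknown McNemar variant {variant!r}")
    return McNemarResult(pair=pair, b=b, c=c, statistic=float(statistic), pvalue=pvalue)


def eligible_pairs(table: TransitionTable) -> list[tuple[PostureLabel, PostureLabel]]:
    """Unordered posture pairs eligible for pairwise testing.

    A pair qualifies only when both discordant counts are strictly
    positive (min(b, c) >= 1).
    """
    out = []
    for i in range(_K):
        for j in range(i + 1, _K):
            b, c = int(table.counts[i, j]), int(table.counts[j, i])
            if min(b, c) >= 1:
                out.append((RECOGNIZED[i], RECOGNIZED[j]))
    return out


@dataclass(frozen=True)
class BowkerResult:
    """Bowker's global chi-square test of transition-table symmetry."""

    statistic: float
    df: int
    pvalue: float


def bowker(table: TransitionTable) -> BowkerResult:
    """Global symmetry test over all pairs with a nonzero discordant sum.

    Statistic: sum of ``(n_ij - n_ji)^2 / (n_ij + n_ji)`` over unordered
    pairs with ``n_ij + n_ji > 0``; degrees of freedom = number of
    included pairs.
    """
    statistic, df = 0.0, 0
    for i in range(_K):
        for j in range(i + 1, _K):
            b, c = int(table.counts[i, j]), int(table.counts[j, i])
            if b + c > 0:
                statistic += (b - c) ** 2 / (b + c)
                df += 1
    if df == 0:
        raise ValueError("fully diagonal table: no discordant pairs to test")
    return BowkerResult(
        statistic=float(statistic), df=df, pvalue=float(stats.chi2.sf(statistic, df=df))
    )


def interval_distribution(
    results: Sequence[ParticipantResult], interval: str
) -> dict[PostureLabel, float]:
    """Proportion of participants per posture in one interval (sums to 1)."""
    if not results:
        raise ValueError("no participants")
    attr = {"TI1": "ti1", "TI2": "ti2", "TI3": "ti3"}[interval]
    counts = {p: 0 for p in RECOGNIZED}
    for r in results:
        if r.status is not ParticipantStatus.OK:
            raise ValueError(f"participant {r.participant} is not OK")
        counts[getattr(r, attr)] += 1
    n = len(results)
    return {p: c / n for p, c in counts.items()}


class TripleClass(enum.Enum):
    """Monotonicity class of a three-interval posture triple."""

    NO_TRANSITION = "NO_TRANSITION"    # same posture in all three intervals
    MONOTONIC = "MONOTONIC"            # moves without revisiting a departed posture
    NON_MONOTONIC = "NON_MONOTONIC"    # returns to a posture it had left


def classify_triple(triple: Sequence[PostureLabel | str]) -> TripleClass:
    """Classify a (TI1, TI2, TI3) posture triple by monotonicity."""
    a, b, c = (PostureLabel.coerce(p) for p in triple)
    if not all(p.is_recognized for p in (a, b, c)):
        raise ValueError("triples must contain recognized postures P1..P8")
    if a == b == c:
        return TripleClass.NO_TRANSITION
    # A departed posture is revisited only as TI1 -> ... -> TI1 with a
    # different posture in between.
    if a == c and a != b:
        return TripleClass.NON_MONOTONIC
    return TripleClass.MONOTONIC


# ---------------------------------------------------------------------------
# display conventions
# ---------------------------------------------------------------------------


def format_pvalue(p: float) -> float:
    """Round a p-value for display: three decimals, four below 0.001.

    Rounding is in two stages — to four decimals first, then to three
    with an exact trailing 5 dropped rather than rounded up. This
    half-down convention at the third decimal matches the reference
    cohort's published tables (e.g. p = 0.47950 prints as 0.479).
    """
    if not 0 <= p <= 1:
        raise ValueError("p-values lie in [0, 1]")
    q4 = Decimal(repr(p)).quantize(Decimal("0.0001"))
    if q4 < Decimal("0.001"):
        return float(q4)
    return float(q4.quantize(Decimal("0.001"), rounding=ROUND_HALF_DOWN))


def significance_band(p: float) -> str:
    """Label a p-value: significant (<0.05), notable (<0.10), or ns."""
    if p < 0.05:
        return "significant"
    if p < 0.10:
        return "notable"
    return "ns"


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class PostureTransitionModel:
    """Paired posture-transition analysis over the three test intervals.

    Parameters
    ----------
    results
        Classified participants; all must have status OK (exclude failed
        and unrecognized recordings first).
    mcnemar_variant
        ``'cc'`` (continuity-corrected chi-square, default),
        ``'uncorrected'``, or ``'exact'``.

    Examples
    --------
    >>> from seatpose import datasets, simulate, transitions
    >>> cohort = simulate.generate_fixture_cohort(
    ...     datasets.cohort_ti1_ti2(), datasets.cohort_ti2_ti3())
    >>> res = transitions.PostureTransitionModel.from_triples(
    ...     [f.triple for f in cohort]).fit()
    >>> res.tables["TI1-TI2"].n
    83
    """

    def __init__(
        self,
        results: Sequence[ParticipantResult],
        mcnemar_variant: str = "cc",
    ) -> None:
        bad = [r.participant for r in results if r.status is not ParticipantStatus.OK]
        if bad:
            raise ValueError(f"non-OK participants present: {bad}")
        if not results:
            raise ValueError("at least one OK participant is required")
        self.results = list(results)
        self.mcnemar_variant = mcnemar_variant

    @classmethod
    def from_triples(
        cls, triples: Sequence[Sequence[PostureLabel | str]], **kwargs
    ) -> "PostureTransitionModel":
        results = [
            ParticipantResult(
                participant=i + 1,
                ti1=PostureLabel.coerce(a),
                ti2=PostureLabel.coerce(b),
                ti3=PostureLabel.coerce(c),
                status=ParticipantStatus.OK,
            )
            for i, (a, b, c) in enumerate(triples)
        ]
        return cls(results, **kwargs)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "PostureTransitionModel":
        """Build from a ``participant, ti1, ti2, ti3[, status]`` table."""
        from .classify import results_from_frame

        results = [
            r for r in results_from_frame(frame) if r.status is ParticipantStatus.OK
        ]
        return cls(results, **kwargs)

    def fit(self) -> "PostureTransitionResults":
        """Compute tables, pairwise tests, symmetry tests and summaries."""
        pairs_spec = [("TI1", "TI2"), ("TI2", "TI3")]
        tables, mcnemar_results, bowker_results = {}, {}, {}
        for a, b in pairs_spec:
            key = f"{a}-{b}"
            table = build_transition_table(self.results, a, b)
            tables[key] = table
            tests = []
            for pair in eligible_pairs(table):
                bb, cc = table.discordant(pair)
                tests.append(mcnemar_cc(bb, cc, pair=pair, variant=self.mcnemar_variant))
            mcnemar_results[key] = tests
            try:
                bowker_results[key] = bowker(table)
            except ValueError:
                # fully diagonal table: symmetry is trivially unrejectable
                bowker_results[key] = None
        distributions = {
            ti: interval_distribution(self.results, ti) for ti in ("TI1", "TI2", "TI3")
        }
        triple_counts = {tc: 0 for tc in TripleClass}
        for r in self.results:
            triple_counts[classify_triple(r.triple)] += 1
        return PostureTransitionResults(
            model=self,
            tables=tables,
            mcnemar=mcnemar_results,
            bowker=bowker_results,
            distributions=distributions,
            triple_counts=triple_counts,
        )


@dataclass(frozen=True)
class PostureTransitionResults:
    """Fitted transition analysis: tables, tests, distributions, triples."""

    model: PostureTransitionModel
    tables: dict[str, TransitionTable]
    mcnemar: dict[str, list[McNemarResult]]
    bowker: dict[str, BowkerResult | None]
    distributions: dict[str, dict[PostureLabel, float]]
    triple_counts: dict[TripleClass, int]

    @property
    def nobs(self) -> int:
        return len(self.model.results)

    def mcnemar_frame(self) -> pd.DataFrame:
        """All pairwise tests as a tidy DataFrame with display p-values."""
        rows = []
        for key, tests in self.mcnemar.items():
            for t in tests:
                rows.append(
                    {
                        "transition": key,
                        "pair": t.pair_name,
                        "b": t.b,
                        "c": t.c,
                        "statistic": t.statistic,
                        "pvalue": t.pvalue,
                        "pvalue_display": format_pvalue(t.pvalue),
                        "band": significance_band(t.pvalue),
                    }
                )
        return pd.DataFrame(rows)

    def to_report(self) -> dict:
        """Structured report with all analysis blocks (JSON-serializable)."""
        return {
            "n_participants": self.nobs,
            "transition_tables": {
                key: {
                    "rows": [p.value for p in RECOGNIZED],
                    "counts": table.counts.tolist(),
                    "n": table.n,
                }
                for key, table in self.tables.items()
            },
            "mcnemar": {
                key: [
                    {
                        "pair": t.pair_name,
                        "b": t.b,
                        "c": t.c,
                        "statistic": round(t.statistic, 6),
                        "p": format_pvalue(t.pvalue),
                        "band": significance_band(t.pvalue),
                    }
                    for t in tests
                ]
                for key, tests in self.mcnemar.items()
            },
            "bowker": {
                key: (
                    None
                    if b is None
                    else {
                        "statistic": round(b.statistic, 6),
                        "df": b.df,
                        "p": format_pvalue(b.pvalue),
                        "band": significance_band(b.pvalue),
                    }
                )
                for key, b in self.bowker.items()
            },
            "distributions": {
                ti: {p.value: round(share, 6) for p, share in dist.items()}
                for ti, dist in self.distributions.items()
            },
            "triples": {tc.value: n for tc, n in self.triple_counts.items()},
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_report(), indent=2, sort_keys=True, **kwargs)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        """Human-readable summary of the fitted transition analysis."""
        lines = [
            "Posture transition analysis",
            "=" * 60,
            f"Participants: {self.nobs}",
            "",
        ]
        for key, table in self.tables.items():
            lines.append(f"Transition {key} (rows: earlier interval)")
            lines.append(table.to_frame().to_string())
            lines.append("")
            lines.append(f"Pairwise McNemar ({key}):")
            for t in self.mcnemar[key]:
                lines.append(
                    f"  {t.pair_name}: b={t.b} c={t.c} "
                    f"chi2={t.statistic:.3f} p={format_pvalue(t.pvalue)} "
                    f"[{significance_band(t.pvalue)}]"
                )
            b = self.bowker[key]
            if b is None:
                lines.append(f"Bowker symmetry ({key}): not testable (diagonal table)")
            else:
                lines.append(
                    f"Bowker symmetry ({key}): chi2={b.statistic:.3f} "
                    f"df={b.df} p={format_pvalue(b.pvalue)}"
                )
            lines.append("")
        for ti, dist in self.distributions.items():
            shares = ", ".join(
                f"{p.value}: {100 * s:.0f}%" for p, s in dist.items() if s > 0
            )
            lines.append(f"{ti} distribution: {shares}")
        lines.append("")
        lines.append(
            "Triples: "
            + ", ".join(f"{tc.value.lower()}={n}" for tc, n in self.triple_counts.items())
        )
        return "\n".join(lines)

    def plot_transition_graph(self, ax=None):
        """Layered transition graph TI1 -> TI2 -> TI3.

        Nodes are postures per interval; edge width is proportional to the
        number of participants making that transition. Requires matplotlib
        and networkx.
        """
        import matplotlib.pyplot as plt
        import networkx as nx

        graph = nx.DiGraph()
        layers = ("TI1", "TI2", "TI3")
        pos = {}
        for x, ti in enumerate(layers):
            for y, p in enumerate(RECOGNIZED):
                node = f"{ti}:{p.value}"
                graph.add_node(node)
                pos[node] = (x, -y)
        for key, table in self.tables.items():
            a, b = key.split("-")
            for i, pi in enumerate(RECOGNIZED):
                for j, pj in enumerate(RECOGNIZED):
                    n = int(table.counts[i, j])
                    if n:
                        graph.add_edge(f"{a}:{pi.value}", f"{b}:{pj.value}", weight=n)
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 6))
        widths = [0.4 * d["weight"] for _, _, d in graph.edges(data=True)]
        nx.draw_networkx(
            graph, pos=pos, ax=ax, node_size=300, font_size=7, arrows=True,
            width=widths, node_color="#cfe2f3", edge_color="#666666",
        )
        ax.set_axis_off()
        return ax


def transition_report(
    results: Sequence[ParticipantResult], mcnemar_variant: str = "cc"
) -> dict:
    """One-call structured report: tables, tests, distributions, triples."""
    model = PostureTransitionModel(results, mcnemar_variant=mcnemar_variant)
    return model.fit().to_report()
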