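"""Labelled-taxon screen for two-fraction DNA-SIP experiments.

The screen asks, per taxon, whether the odds of a read belonging to that
taxon in the heavy versus the light gradient fraction differ between the
unlabelled (12C) and labelled (13C) incubations. For each isotope stratum
``s`` the 2x2 table is

    ================  ==============  ================
    stratum s         focal taxon      all other taxa
    ================  ==============  ================
    heavy fraction    G_H(s)           nG_H(s)
    light fraction    G_L(s)           nG_L(s)
    ================  ==============  ================

with the odds ratio OR(s) = (G_H/nG_H) / (G_L/nG_L). Isotope incorporation
shifts a taxon's DNA to denser gradient positions, so a labelled taxon shows
OR(C13) > OR(C12); homogeneity of the two odds ratios is tested with the
Breslow-Day chi-square statistic built around the Mantel-Haenszel pooled
odds ratio. Raw counts are used directly — the test conditions on per-sample
totals, so no rarefaction or relative-abundance transform is applied and
statistical power grows with sequencing depth.

Family-wise error over the thousands of taxa tested in one treatment is
controlled with the Holm step-down rule: with the p-values sorted
ascending, the k-th is rejected iff p(k) < alpha/(n+1-k) and all smaller
p-values were rejected.

The module-level functions expose each step; :class:`LabelScreen` /
:class:`LabelScreenResults` wrap them in a fit-style interface.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, UndefinedStatisticError, ValidationError
from .io import RANKS, SipCountTable, TaxonomyMap, write_label_report

__all__ = [
    "ContingencyPair",
    "OddsRatioPair",
    "BreslowDayResult",
    "HolmDecision",
    "LabelCall",
    "LabelScreen",
    "LabelScreenResults",
    "build_contingency",
    "odds_ratio",
    "mh_common_odds_ratio",
    "breslow_day",
    "holm_bonferroni",
    "classify_label",
    "run_labelling_screen",
    "aggregate_labelled_taxa",
]

logger = logging.getLogger(__name__)

Correction = Literal["haldane", "strict"]

STRATA = ("C12", "C13")


@dataclass(frozen=True)
class ContingencyPair:
    """The two stratified 2x2 tables for one taxon.

    Each stratum is ``(G_H, nG_H, G_L, nG_L)``: reads of the focal taxon /
    of all other taxa, in the heavy / light fraction sample of that isotope
    incubation.
    """

    c12: tuple[float, float, float, float]
    c13: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        for name, cells in self.strata():
            if len(cells) != 4:
                raise ValidationError(f"stratum {name}: expected 4 cells")
            if any(x < 0 for x in cells):
                raise ValidationError(f"stratum {name}: negative cell in {cells}")

    def strata(self) -> list[tuple[str, tuple[float, float, float, float]]]:
        return [("C12", self.c12), ("C13", self.c13)]


@dataclass(frozen=True)
class OddsRatioPair:
    """Heavy/light odds ratios in each isotope stratum.

    ``corrected`` flags that the Haldane-Anscombe continuity correction
    (adding 0.5 to all four cells of a stratum containing a zero) was applied
    in at least one stratum.
    """

    or_c12: float
    or_c13: float
    corrected: bool = False


@dataclass(frozen=True)
class BreslowDayResult:
    """Breslow-Day homogeneity test result.

    ``expected_a`` holds the per-stratum fitted heavy-fraction count of the
    focal taxon under a common odds ratio; ``variance_a`` the corresponding
    asymptotic variances. ``common_or`` is the Mantel-Haenszel pooled OR the
    fit is anchored to.
    """

    statistic: float
    df: int
    p_value: float
    common_or: float
    expected_a: tuple[float, ...]
    variance_a: tuple[float, ...]
    tarone: bool = False


class HolmDecision(NamedTuple):
    """Step-down decision for one hypothesis, in input order."""

    p_value: float
    rank: int  # 1-based rank of the p-value, ascending
    threshold: float  # alpha / (n + 1 - rank)
    reject: bool


@dataclass(frozen=True)
class LabelCall:
    """Final per-taxon call of the screen."""

    otu_id: str
    odds_ratios: OddsRatioPair
    bd: BreslowDayResult
    p_raw: float
    holm_rank: int
    holm_threshold: float
    significant: bool
    direction: str  # "labelled" | "unlabelled" | "none"


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------


def _apply_correction(
    cells: Sequence[float], correction: Correction
) -> tuple[tuple[float, float, float, float], bool]:
    """Resolve zero cells per the continuity-correction policy.

    haldane: if any of the four cells is 0, add 0.5 to all four (Haldane-
    Anscombe), keeping every statistic finite. strict: zero cells are left
    in place and downstream operations raise.
    """
    cells = tuple(float(x) for x in cells)
    if any(x < 0 for x in cells):
        raise ValidationError(f"negative cell in {cells}")
    if all(x == 0 for x in cells):
        raise UndefinedStatisticError("all four cells are zero; odds ratio undefined")
    if correction not in ("haldane", "strict"):
        raise ValidationError(f"unknown correction policy {correction!r}")
    if any(x == 0 for x in cells):
        if correction == "strict":
            raise UndefinedStatisticError(
                f"zero cell in {cells} with correction='strict'; use the "
                "haldane policy to continuity-correct"
            )
        return tuple(x + 0.5 for x in cells), True
    return cells, False


def odds_ratio(
    g_h: float, ng_h: float, g_l: float, ng_l: float, correction: Correction = "haldane"
) -> float:
    """Sample odds ratio (G_H/nG_H)/(G_L/nG_L) for one stratum.

    Under the default ``haldane`` policy a zero anywhere triggers adding 0.5
    to all four cells first, so the result is always finite and positive.
    """
    (a, b, c, d), _ = _apply_correction((g_h, ng_h, g_l, ng_l), correction)
    return (a / b) / (c / d)


def _corrected_strata(
    pair: ContingencyPair, correction: Correction
) -> tuple[list[tuple[float, float, float, float]], bool]:
    """Continuity-correct each stratum; all-empty strata are excluded
    (an incubation with no reads at all carries no information)."""
    out = []
    corrected = False
    for _, cells in pair.strata():
        if all(x == 0 for x in cells):
            continue
        cells, flag = _apply_correction(cells, correction)
        corrected = corrected or flag
        out.append(cells)
    if not out:
        raise UndefinedStatisticError("every stratum is empty; nothing to test")
    return out, corrected


def mh_common_odds_ratio(pair: ContingencyPair, correction: Correction = "haldane") -> float:
    """Mantel-Haenszel pooled odds ratio across the two isotope strata.

    sum_s(a_s d_s / N_s) / sum_s(b_s c_s / N_s) with (a,b,c,d) =
    (G_H, nG_H, G_L, nG_L) and N_s the stratum total. Reduces to the sample
    OR when only one stratum has data.
    """
    strata, _ = _corrected_strata(pair, correction)
    num = 0.0
    den = 0.0
    for a, b, c, d in strata:
        n = a + b + c + d
        if n == 0:
            continue
        num += a * d / n
        den += b * c / n
    if den == 0 or num == 0:
        raise UndefinedStatisticError(
            "Mantel-Haenszel odds ratio undefined: zero numerator or denominator"
        )
    return num / den


def _bd_expected_count(r1: float, c1: float, n: float, common_or: float) -> float:
    """Fitted heavy-fraction focal count under a common odds ratio.

    Solves R = a(n - r1 - c1 + a) / ((r1 - a)(c1 - a)) for the admissible
    root a in (max(0, r1 + c1 - n), min(r1, c1)); r1 = heavy-row total,
    c1 = focal-taxon column total.
    """
    lo = max(0.0, r1 + c1 - n)
    hi = min(r1, c1)
    if not (lo < hi):
        raise UndefinedStatisticError(
            f"degenerate 2x2 margins (row total {r1}, column total {c1}, "
            f"N {n}); apply the haldane correction policy"
        )
    r = common_or
    if abs(r - 1.0) < 1e-12:
        return r1 * c1 / n
    # (R-1) a^2 - [R(r1+c1) + (n - r1 - c1)] a + R r1 c1 = 0
    qa = r - 1.0
    qb = -(r * (r1 + c1) + (n - r1 - c1))
    qc = r * r1 * c1
    disc = qb * qb - 4.0 * qa * qc
    disc = max(disc, 0.0)
    sq = math.sqrt(disc)
    # numerically stable pair of roots
    if qb >= 0:
        root1 = (-qb - sq) / (2.0 * qa)
    else:
        root1 = (-qb + sq) / (2.0 * qa)
    root2 = qc / (qa * root1)
    candidates = [x for x in (root1, root2) if lo < x < hi]
    if not candidates:
        # fall back to the closest root; margins of float width can exclude both
        candidates = sorted((root1, root2), key=lambda x: abs(x - 0.5 * (lo + hi)))
    return candidates[0]


def breslow_day(
    pair: ContingencyPair,
    tarone: bool = False,
    correction: Correction = "haldane",
) -> BreslowDayResult:
    """Breslow-Day test of odds-ratio homogeneity across the two strata.

    For each stratum the focal-taxon heavy count fitted under the
    Mantel-Haenszel common OR is found as the admissible root of a quadratic;
    the statistic sums squared deviations of observed from fitted counts over
    the asymptotic variances

        Var_s = 1 / (1/a~ + 1/(r1-a~) + 1/(c1-a~) + 1/(N-r1-c1+a~))

    and is referred to chi-square with (strata - 1) = 1 degree of freedom.
    With ``tarone=True`` the Tarone correction term
    (sum(a - a~))^2 / sum(Var) is subtracted.
    """
    strata, _ = _corrected_strata(pair, correction)
    if len(strata) < 2:
        raise UndefinedStatisticError(
            "Breslow-Day test needs at least two non-empty strata (df = 0 otherwise)"
        )
    common = mh_common_odds_ratio(pair, correction)
    statistic = 0.0
    dev_sum = 0.0
    var_sum = 0.0
    expected = []
    variances = []
    for a, b, c, d in strata:
        n = a + b + c + d
        r1 = a + b  # heavy-fraction sample total
        c1 = a + c  # focal-taxon total
        a_fit = _bd_expected_count(r1, c1, n, common)
        var = 1.0 / (
            1.0 / a_fit
            + 1.0 / (r1 - a_fit)
            + 1.0 / (c1 - a_fit)
            + 1.0 / (n - r1 - c1 + a_fit)
        )
        expected.append(a_fit)
        variances.append(var)
        statistic += (a - a_fit) ** 2 / var
        dev_sum += a - a_fit
        var_sum += var
    if tarone:
        statistic -= dev_sum**2 / var_sum
    statistic = max(statistic, 0.0)
    df = len(strata) - 1
    p = float(stats.chi2.sf(statistic, df))
    return BreslowDayResult(
        statistic=float(statistic),
        df=df,
        p_value=p,
        common_or=float(common),
        expected_a=tuple(expected),
        variance_a=tuple(variances),
        tarone=tarone,
    )


def holm_bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> list[HolmDecision]:
    """Holm step-down multiple-testing decisions.

    The k-th smallest p-value is rejected iff p(k) < alpha/(n+1-k) and every
    smaller p-value was rejected (first failure stops the step-down). Ties
    are ranked stably in input order. Equality with the threshold is not
    rejected. Decisions are returned in input order.
    """
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    p = list(map(float, p_values))
    for x in p:
        if not (0.0 <= x <= 1.0) or math.isnan(x):
            raise ValidationError(f"p-value {x} outside [0, 1]")
    n = len(p)
    order = sorted(range(n), key=lambda i: (p[i], i))  # stable tie-break
    decisions: list[HolmDecision | None] = [None] * n
    rejecting = True
    for k, idx in enumerate(order, start=1):
        threshold = alpha / (n + 1 - k)
        reject = rejecting and p[idx] < threshold
        if not reject:
            rejecting = False
        decisions[idx] = HolmDecision(p[idx], k, threshold, reject)
    return decisions  # type: ignore[return-value]


def classify_label(or_pair: OddsRatioPair, significant: bool) -> str:
    """Direction of a significant odds-ratio difference.

    ``labelled``: OR(C13) > OR(C12) — the taxon is over-represented in the
    heavy fraction of the labelled incubation, i.e. it incorporated the
    isotope. ``unlabelled``: OR(C13) < OR(C12) — relatively enriched in the
    light fraction of the labelled incubation. Non-significant calls, and the
    measure-zero exact tie, are ``none``.
    """
    if not significant:
        return "none"
    if or_pair.or_c13 > or_pair.or_c12:
        return "labelled"
    if or_pair.or_c13 < or_pair.or_c12:
        return "unlabelled"
    return "none"


# ---------------------------------------------------------------------------
# table plumbing
# ---------------------------------------------------------------------------


def _required_samples(table: SipCountTable, treatment: str | None) -> dict[tuple[str, str], str]:
    if table.meta is None:
        raise ConfigurationError(
            "count table carries no fraction metadata; attach FractionMeta "
            "(isotope, fraction_role, treatment) before screening"
        )
    if treatment is None:
        treatments = table.treatments()
        if len(treatments) != 1:
            raise ConfigurationError(
                f"treatment must be given when the table holds several: {treatments}"
            )
        treatment = treatments[0]
    layout: dict[tuple[str, str], str] = {}
    for isotope in ("C12", "C13"):
        for role in ("heavy", "light"):
            sid = table.find_sample(isotope, role, treatment)
            if sid is None:
                raise ConfigurationError(
                    f"missing sample for isotope={isotope}, fraction_role={role}, "
                    f"treatment={treatment!r}"
                )
            layout[(isotope, role)] = sid
    return layout


def build_contingency(
    table: SipCountTable, otu_id: str, treatment: str | None = None
) -> ContingencyPair:
    """Stratified 2x2 counts for one taxon from the four fraction samples."""
    if otu_id not in table.otu_ids:
        raise ValidationError(f"OTU {otu_id!r} not present in the count table")
    layout = _required_samples(table, treatment)
    totals = table.sample_totals()
    row = table.counts[table.otu_ids.index(otu_id)]
    idx = {sid: j for j, sid in enumerate(table.sample_ids)}

    def cells(isotope: str) -> tuple[float, float, float, float]:
        h = layout[(isotope, "heavy")]
        l = layout[(isotope, "light")]
        g_h = float(row[idx[h]])
        g_l = float(row[idx[l]])
        return g_h, float(totals[h]) - g_h, g_l, float(totals[l]) - g_l

    return ContingencyPair(c12=cells("C12"), c13=cells("C13"))


# ---------------------------------------------------------------------------
# the screen
# ---------------------------------------------------------------------------


def run_labelling_screen(
    table: SipCountTable,
    treatment: str | None = None,
    alpha: float = 0.05,
    correction: Correction = "haldane",
    tarone: bool = False,
    min_total: int = 0,
) -> list[LabelCall]:
    """Screen every taxon of one treatment for isotope labelling.

    Raw counts are used directly (no subsampling or normalisation). Taxa
    with zero reads across the four fraction samples are skipped, as are
    taxa whose four-sample read total is below ``min_total`` (default 0 =
    test everything). The Holm family size n is the number of taxa actually
    tested. Calls are returned ordered by raw p ascending, ties by OTU id.
    """
    layout = _required_samples(table, treatment)
    totals = table.sample_totals()
    cols = {key: table.sample_ids.index(sid) for key, sid in layout.items()}
    tot = {key: float(totals[sid]) for key, sid in layout.items()}

    stubs: list[tuple[str, OddsRatioPair, BreslowDayResult]] = []
    n_skipped = 0
    for i, otu in enumerate(table.otu_ids):
        row = table.counts[i]
        g = {key: float(row[j]) for key, j in cols.items()}
        four_total = sum(g.values())
        if four_total == 0 or four_total < min_total:
            n_skipped += 1
            continue
        pair = ContingencyPair(
            c12=(
                g[("C12", "heavy")],
                tot[("C12", "heavy")] - g[("C12", "heavy")],
                g[("C12", "light")],
                tot[("C12", "light")] - g[("C12", "light")],
            ),
            c13=(
                g[("C13", "heavy")],
                tot[("C13", "heavy")] - g[("C13", "heavy")],
                g[("C13", "light")],
                tot[("C13", "light")] - g[("C13", "light")],
            ),
        )
        (a12, b12, c12_, d12), f1 = _apply_correction(pair.c12, correction)
        (a13, b13, c13_, d13), f2 = _apply_correction(pair.c13, correction)
        ors = OddsRatioPair(
            or_c12=(a12 / b12) / (c12_ / d12),
            or_c13=(a13 / b13) / (c13_ / d13),
            corrected=f1 or f2,
        )
        bd = breslow_day(pair, tarone=tarone, correction=correction)
        stubs.append((otu, ors, bd))
    if n_skipped:
        logger.info(
            "skipped %d taxa (all-zero across the four samples or below min_total=%d)",
            n_skipped,
            min_total,
        )

    # deterministic ranking: raw p ascending, ties by OTU id
    stubs.sort(key=lambda s: (s[2].p_value, s[0]))
    decisions = holm_bonferroni([s[2].p_value for s in stubs], alpha=alpha)
    calls = []
    for (otu, ors, bd), dec in zip(stubs, decisions):
        calls.append(
            LabelCall(
                otu_id=otu,
                odds_ratios=ors,
                bd=bd,
                p_raw=bd.p_value,
                holm_rank=dec.rank,
                holm_threshold=dec.threshold,
                significant=dec.reject,
                direction=classify_label(ors, dec.reject),
            )
        )
    return calls


def aggregate_labelled_taxa(
    calls: Iterable[LabelCall],
    taxonomy: TaxonomyMap,
    rank: str,
    table: SipCountTable,
    treatment: str | None = None,
) -> pd.Series:
    """Relative abundance per taxonomic group among labelled taxa.

    Sums the 13C-heavy-sample reads of taxa called ``labelled`` per group at
    ``rank`` and normalises to 1 over the labelled set — the composition of
    the isotope-assimilating community as seen in the heavy fraction.
    Returns an empty Series when nothing is labelled.
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labelled = [c.otu_id for c in calls if c.direction == "labelled"]
    if not labelled:
        return pd.Series(dtype=float, name=rank)
    layout = _required_samples(table, treatment)
    heavy13 = table.column(layout[("C13", "heavy")])
    idx = {otu: i for i, otu in enumerate(table.otu_ids)}
    sums: dict[str, float] = {}
    for otu in labelled:
        group = taxonomy.rank_of(otu, rank)
        sums[group] = sums.get(group, 0.0) + float(heavy13[idx[otu]])
    out = pd.Series(sums, name=rank).sort_index()
    total = out.sum()
    if total > 0:
        out = out / total
    return out


# ---------------------------------------------------------------------------
# model / results interface
# ---------------------------------------------------------------------------


class LabelScreen:
    """Labelling screen as a fit-style model over a :class:`SipCountTable`.

    Parameters
    ----------
    table
        Count table annotated with :class:`~sipscreen.io.FractionMeta`.
    treatment
        Treatment to screen; may be omitted when the table holds only one.
    alpha
        Family-wise error level for the Holm step-down (default 0.05).
    correction
        Zero-cell policy: ``"haldane"`` (add 0.5 to all cells of a stratum
        containing a zero) or ``"strict"`` (raise).
    tarone
        Apply the Tarone adjustment to the Breslow-Day statistic.
    min_total
        Minimum four-sample read total for a taxon to be tested.
    """

    def __init__(
        self,
        table: SipCountTable,
        treatment: str | None = None,
        alpha: float = 0.05,
        correction: Correction = "haldane",
        tarone: bool = False,
        min_total: int = 0,
    ) -> None:
        if not (0.0 < alpha < 1.0):
            raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
        self.table = table
        self.treatment = treatment
        self.alpha = alpha
        self.correction = correction
        self.tarone = tarone
        self.min_total = min_total

    @classmethod
    def from_dataframe(
        cls,
        counts,
        meta,
        **kwargs,
    ) -> "LabelScreen":
        """Build from a taxa x samples DataFrame and a sample->FractionMeta map."""
        return cls(SipCountTable.from_frame(counts, meta=meta), **kwargs)

    def fit(self) -> "LabelScreenResults":
        calls = run_labelling_screen(
            self.table,
            treatment=self.treatment,
            alpha=self.alpha,
            correction=self.correction,
            tarone=self.tarone,
            min_total=self.min_total,
        )
        return LabelScreenResults(self, calls)


class LabelScreenResults:
    """Results of :meth:`LabelScreen.fit`: one :class:`LabelCall` per taxon."""

    def __init__(self, model: LabelScreen, calls: list[LabelCall]) -> None:
        self.model = model
        self.calls = calls

    @property
    def n_tested(self) -> int:
        return len(self.calls)

    @property
    def labelled(self) -> list[LabelCall]:
        return [c for c in self.calls if c.direction == "labelled"]

    @property
    def unlabelled(self) -> list[LabelCall]:
        return [c for c in self.calls if c.direction == "unlabelled"]

    def to_frame(self) -> pd.DataFrame:
        """Calls as a DataFrame ordered by Holm rank."""
        return pd.DataFrame(
            {
                "otu_id": [c.otu_id for c in self.calls],
                "or_c12": [c.odds_ratios.or_c12 for c in self.calls],
                "or_c13": [c.odds_ratios.or_c13 for c in self.calls],
                "bd_statistic": [c.bd.statistic for c in self.calls],
                "p_value": [c.p_raw for c in self.calls],
                "holm_rank": [c.holm_rank for c in self.calls],
                "holm_threshold": [c.holm_threshold for c in self.calls],
                "significant": [c.significant for c in self.calls],
                "direction": [c.direction for c in self.calls],
            }
        ).set_index("otu_id")

    def aggregate(self, taxonomy: TaxonomyMap, rank: str = "class") -> pd.Series:
        """Relative abundance of labelled taxa per group at ``rank``."""
        return aggregate_labelled_taxa(
            self.calls, taxonomy, rank, self.model.table, self.model.treatment
        )

    def write_report(self, path, taxonomy: TaxonomyMap | None = None) -> pd.DataFrame:
        """Write the TSV labelling report (see :func:`sipscreen.io.write_label_report`)."""
        return write_label_report(self.calls, taxonomy, path)

    def summary(self) -> str:
        """Plain-text summary of the screen."""
        n_lab = len(self.labelled)
        n_unlab = len(self.unlabelled)
        n_sig = sum(c.significant for c in self.calls)
        lines = [
            "Labelling screen (heavy/light odds-ratio homogeneity)",
            "=" * 54,
            f"taxa tested:            {self.n_tested}",
            f"alpha (Holm, FWER):     {self.model.alpha}",
            f"correction policy:      {self.model.correction}"
            + (" + Tarone" if self.model.tarone else ""),
            f"significant taxa:       {n_sig}",
            f"  labelled (13C-heavy): {n_lab}",
            f"  unlabelled (light):   {n_unlab}",
        ]
        if n_lab:
            lines.append("")
            lines.append("top labelled taxa (by p-value):")
            lines.append(f"{'otu':<16}{'OR 12C':>10}{'OR 13C':>10}{'p':>12}")
            for c in self.labelled[:10]:
                lines.append(
                    f"{c.otu_id:<16}{c.odds_ratios.or_c12:>10.3g}"
                    f"{c.odds_ratios.or_c13:>10.3g}{c.p_raw:>12.3g}"
                )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<LabelScreenResults: {self.n_tested} taxa tested, "
            f"{len(self.labelled)} labelled, {len(self.unlabelled)} unlabelled>"
        )
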