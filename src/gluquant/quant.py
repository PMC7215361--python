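"""Differential glutathionylation from ICAT heavy:light peptide ratios.

The quantitative model: for a cysteine site with glutathionylation occupancy
θ, the heavy:light ratio measures the glutathionylated-to-reduced thiol
ratio r = θ/(1−θ).  Per peptide, the pipeline

1. filters observations (identification confidence ≥ 95%, H:L ≥ 0.01),
2. collapses technical replicates to one value per subject,
3. averages subjects within case and control groups,
4. forms the ratio-of-ratios RoR = mean(case H:L) / mean(control H:L),
5. tests case vs control subject values with a two-sided Mann–Whitney test,
6. calls a peptide differentially glutathionylated when RoR strictly
   exceeds the fold cutoff (default 1.5) and p < alpha (default 0.05),
7. rolls peptide calls up to proteins (a protein is significant when at
   least one of its peptides is).

Threshold semantics follow the wording that defined them: the confidence and
ratio floors are inclusive ("at least"), the fold cutoff is strict
("exceeded"), and alpha is strict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import (
    CASE,
    CONTROL,
    PeptideMeasurement,
    ProteinRecord,
    UnmappedPeptideError,
    map_peptide_to_protein,
)

ARITHMETIC = "arithmetic"
GEOMETRIC = "geometric"
MTC_NONE = "none"
MTC_BH = "benjamini_hochberg"


@dataclass(frozen=True)
class QuantConfig:
    """Thresholds and options of the differential pipeline.

    Defaults mirror the analysis constants of the original ICAT workflow:
    95% identification confidence, an H:L floor of 0.01 (below which ratios
    are noise), a 1.5-fold ratio-of-ratios cutoff, and alpha 0.05 with no
    multiple-testing correction (Benjamini–Hochberg available by flag).
    """

    min_confidence_pct: float = 95.0
    min_h_to_l: float = 0.01
    fold_cutoff: float = 1.5
    alpha: float = 0.05
    min_subjects_per_group: int = 3
    mean_kind: str = ARITHMETIC
    mtc: str = MTC_NONE
    exact_test_max_n: int = 12
    two_sided_calls: bool = False  # also call RoR < 1/fold_cutoff

    def __post_init__(self) -> None:
        if self.min_confidence_pct < 0 or self.min_h_to_l <= 0:
            raise ValueError("thresholds must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.fold_cutoff <= 1.0:
            raise ValueError("fold_cutoff must exceed 1")
        if self.mean_kind not in (ARITHMETIC, GEOMETRIC):
            raise ValueError(f"unknown mean_kind {self.mean_kind!r}")
        if self.mtc not in (MTC_NONE, MTC_BH):
            raise ValueError(f"unknown mtc {self.mtc!r}")
        if self.min_subjects_per_group < 1:
            raise ValueError("min_subjects_per_group must be >= 1")


@dataclass
class FilterLog:
    """Per-criterion rejection counts from :func:`filter_peptides`.

    A row failing both criteria is counted under each; ``n_rejected`` counts
    rows failing at least one.
    """

    n_input: int = 0
    n_low_confidence: int = 0
    n_low_ratio: int = 0
    n_rejected: int = 0
    n_retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass(frozen=True)
class GroupSummary:
    """Per-group summary of one peptide: subject-level H:L values and mean."""

    key: tuple[str, str, tuple[int, ...]]
    group: str
    subject_values: tuple[float, ...]
    group_mean: float

    @property
    def n_subjects(self) -> int:
        return len(self.subject_values)


@dataclass(frozen=True)
class DifferentialCall:
    """Differential decision for one peptide."""

    key: tuple[str, str, tuple[int, ...]]
    ratio_of_ratios: float
    p_value: float
    q_value: float | None
    passes_fold: bool
    passes_p: bool
    significant: bool


@dataclass(frozen=True)
class ProteinCall:
    """Protein-level rollup of peptide calls (any-peptide rule)."""

    accession: str
    n_peptides_total: int
    n_peptides_significant: int
    significant: bool
    best_ratio_of_ratios: float
    best_p_value: float


class InsufficientSubjectsError(ValueError):
    """A peptide was observed in fewer subjects than the configured minimum."""


# ---------------------------------------------------------------------------
# Stage 1: filtering
# ---------------------------------------------------------------------------

def filter_peptides(
    measurements: Iterable[PeptideMeasurement],
    config: QuantConfig = QuantConfig(),
) -> tuple[list[PeptideMeasurement], FilterLog]:
    """Keep observations with confidence ≥ floor and H:L ≥ floor (inclusive)."""
    log = FilterLog()
    kept: list[PeptideMeasurement] = []
    for m in measurements:
        log.n_input += 1
        low_conf = m.confidence_pct < config.min_confidence_pct
        low_ratio = m.h_to_l < config.min_h_to_l
        if low_conf:
            log.n_low_confidence += 1
        if low_ratio:
            log.n_low_ratio += 1
        if low_conf or low_ratio:
            log.n_rejected += 1
        else:
            kept.append(m)
            log.n_retained += 1
    return kept, log


# ---------------------------------------------------------------------------
# Stage 2: technical-replicate collapse
# ---------------------------------------------------------------------------

def collapse_technical_replicates(
    measurements: Sequence[PeptideMeasurement],
) -> pd.DataFrame:
    """Average technical replicates to one H:L value per (peptide, subject).

    Treating duplicates as independent observations would pseudo-replicate
    the group comparison, so replicates are collapsed by arithmetic mean
    before any group statistic.  Subjects with a single observation pass
    through unchanged.

    Returns a frame with columns accession, peptide, cys_positions (";"
    joined), group, subject_id, h_to_l, n_replicates.
    """
    if not measurements:
        return pd.DataFrame(
            columns=[
                "accession",
                "peptide",
                "cys_positions",
                "group",
                "subject_id",
                "h_to_l",
                "n_replicates",
            ]
        )
    df = pd.DataFrame(
        {
            "accession": [m.accession for m in measurements],
            "peptide": [m.peptide_sequence for m in measurements],
            "cys_positions": [
                ";".join(str(p) for p in m.peptide_cys_positions)
                for m in measurements
            ],
            "group": [m.group for m in measurements],
            "subject_id": [m.subject_id for m in measurements],
            "h_to_l": [m.h_to_l for m in measurements],
        }
    )
    out = (
        df.groupby(
            ["accession", "peptide", "cys_positions", "group", "subject_id"],
            sort=True,
        )["h_to_l"]
        .agg(h_to_l="mean", n_replicates="size")
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# Stage 3: group summaries
# ---------------------------------------------------------------------------

def summarize_group(
    subject_values: Sequence[float],
    key: tuple[str, str, tuple[int, ...]],
    group: str,
    config: QuantConfig = QuantConfig(),
) -> GroupSummary:
    """Average per-subject H:L values within one group.

    Raises :class:`InsufficientSubjectsError` below the subject minimum;
    callers exclude the peptide from the comparison and log the reason.
    """
    values = tuple(float(v) for v in subject_values)
    if len(values) < config.min_subjects_per_group:
        raise InsufficientSubjectsError(
            f"insufficient observations: {len(values)} subject(s) in {group} "
            f"group for {key}, minimum {config.min_subjects_per_group}"
        )
    if config.mean_kind == ARITHMETIC:
        mean = float(np.mean(values))
    else:
        mean = float(np.exp(np.mean(np.log(values))))
    return GroupSummary(key=key, group=group, subject_values=values, group_mean=mean)


# ---------------------------------------------------------------------------
# Stage 4: ratio-of-ratios
# ---------------------------------------------------------------------------

def ratio_of_ratios(case_summary: GroupSummary, control_summary: GroupSummary) -> float:
    """RoR = case group mean / control group mean (dimensionless)."""
    c = control_summary.group_mean
    if not (math.isfinite(c) and c > 0):
        raise ValueError("undefined ratio: control group mean is zero or missing")
    return case_summary.group_mean / c


# ---------------------------------------------------------------------------
# Stage 5: Mann–Whitney test
# ---------------------------------------------------------------------------

def mann_whitney_p(
    values_a: Sequence[float],
    values_b: Sequence[float],
    exact_test_max_n: int = 12,
) -> float:
    """Two-sided Mann–Whitney p-value for two groups of subject values.

    Exact permutation distribution of the U statistic when the pooled sample
    is tie-free and no larger than ``exact_test_max_n``; otherwise the
    midrank normal approximation with tie and continuity corrections.
    The returned p is clipped to (0, 1].
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        return 1.0  # no separation possible
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and pooled.size <= exact_test_max_n:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    p = float(res.pvalue)
    if math.isnan(p):
        return 1.0
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


# ---------------------------------------------------------------------------
# Stage 6: differential calls
# ---------------------------------------------------------------------------

def call_differential(
    case_summary: GroupSummary,
    control_summary: GroupSummary,
    p_value: float,
    config: QuantConfig = QuantConfig(),
    q_value: float | None = None,
) -> DifferentialCall:
    """Combine fold and significance criteria into one call.

    Fold passes on strict RoR > cutoff (only increased glutathionylation is
    called by default; ``two_sided_calls`` adds RoR < 1/cutoff).  The p
    criterion is strict < alpha, applied to the q-value when multiple-testing
    correction is enabled.
    """
    ror = ratio_of_ratios(case_summary, control_summary)
    passes_fold = ror > config.fold_cutoff
    if config.two_sided_calls:
        passes_fold = passes_fold or ror < 1.0 / config.fold_cutoff
    p_for_call = q_value if (config.mtc == MTC_BH and q_value is not None) else p_value
    passes_p = p_for_call < config.alpha
    return DifferentialCall(
        key=case_summary.key,
        ratio_of_ratios=ror,
        p_value=p_value,
        q_value=q_value,
        passes_fold=passes_fold,
        passes_p=passes_p,
        significant=passes_fold and passes_p,
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg q-values (monotone, never below their p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Stage 7: protein rollup
# ---------------------------------------------------------------------------

def rollup_to_proteins(calls: Sequence[DifferentialCall]) -> list[ProteinCall]:
    """Group peptide calls by protein accession (any-peptide rule).

    A protein is significant iff at least one constituent peptide is;
    ``best_ratio_of_ratios`` is the maximum RoR among its peptides and
    ``best_p_value`` the minimum p.  Output is sorted by accession.
    """
    by_acc: dict[str, list[DifferentialCall]] = {}
    for call in calls:
        by_acc.setdefault(call.key[0], []).append(call)
    out = []
    for acc in sorted(by_acc):
        group = by_acc[acc]
        n_sig = sum(c.significant for c in group)
        out.append(
            ProteinCall(
                accession=acc,
                n_peptides_total=len(group),
                n_peptides_significant=n_sig,
                significant=n_sig >= 1,
                best_ratio_of_ratios=max(c.ratio_of_ratios for c in group),
                best_p_value=min(c.p_value for c in group),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Occupancy transform
# ---------------------------------------------------------------------------

def occupancy_from_ratio(r: float) -> float:
    """Site occupancy θ from the H:L ratio: θ = r / (1 + r)."""
    if r < 0:
        raise ValueError("H:L ratio must be nonnegative")
    return r / (1.0 + r)


def ratio_from_occupancy(theta: float) -> float:
    """H:L ratio from site occupancy: r = θ / (1 − θ); θ = 1 is unbounded."""
    if not (0.0 <= theta < 1.0):
        raise ValueError("occupancy must lie in [0, 1); ratio unbounded at 1")
    return theta / (1.0 - theta)


# ---------------------------------------------------------------------------
# Driver: full peptide-table analysis
# ---------------------------------------------------------------------------

@dataclass
class QuantResult:
    """Everything the differential analysis produces for one comparison."""

    peptide_calls: pd.DataFrame
    protein_calls: pd.DataFrame
    site_calls: pd.DataFrame | None
    filter_log: FilterLog
    n_excluded_insufficient: int
    excluded_keys: list[tuple[str, str, str]] = field(default_factory=list)
    unmapped_accessions: list[str] = field(default_factory=list)

    @property
    def n_peptides_tested(self) -> int:
        return len(self.peptide_calls)


def _calls_to_frame(
    rows: list[dict],
) -> pd.DataFrame:
    cols = [
        "accession",
        "peptide",
        "cys_positions",
        "n_case_subjects",
        "n_control_subjects",
        "case_mean",
        "control_mean",
        "ratio_of_ratios",
        "p_value",
        "q_value",
        "passes_fold",
        "passes_p",
        "significant",
    ]
    return pd.DataFrame(rows, columns=cols)


def run_differential(
    measurements: Sequence[PeptideMeasurement],
    config: QuantConfig = QuantConfig(),
    proteins: Mapping[str, ProteinRecord] | None = None,
) -> QuantResult:
    """Run the full peptide-table comparison: filter → collapse → test → call.

    When ``proteins`` is supplied, peptide calls are additionally expanded to
    cysteine-site calls via exact substring mapping; accessions missing from
    the database are retained at peptide/protein level and reported in
    ``unmapped_accessions``.
    """
    kept, flog = filter_peptides(measurements, config)
    per_subject = collapse_technical_replicates(kept)

    rows: list[dict] = []
    summaries: dict[tuple[str, str, str], tuple[GroupSummary, GroupSummary]] = {}
    excluded: list[tuple[str, str, str]] = []
    n_excluded = 0
    if len(per_subject):
        for (acc, pep, cys), sub in per_subject.groupby(
            ["accession", "peptide", "cys_positions"], sort=True
        ):
            key = (acc, pep, tuple(int(x) for x in cys.split(";")) if cys else ())
            case_vals = sub.loc[sub["group"] == CASE, "h_to_l"].to_numpy()
            ctrl_vals = sub.loc[sub["group"] == CONTROL, "h_to_l"].to_numpy()
            try:
                cs = summarize_group(case_vals, key, CASE, config)
                ts = summarize_group(ctrl_vals, key, CONTROL, config)
            except InsufficientSubjectsError:
                n_excluded += 1
                excluded.append((acc, pep, cys))
                continue
            summaries[(acc, pep, cys)] = (cs, ts)

    p_values = {}
    for k, (cs, ts) in summaries.items():
        p_values[k] = mann_whitney_p(
            cs.subject_values, ts.subject_values, config.exact_test_max_n
        )
    q_map: dict[tuple[str, str, str], float | None] = {k: None for k in summaries}
    if config.mtc == MTC_BH and p_values:
        keys = sorted(p_values)
        qs = benjamini_hochberg([p_values[k] for k in keys])
        q_map = dict(zip(keys, (float(q) for q in qs)))

    calls: list[DifferentialCall] = []
    for (acc, pep, cys), (cs, ts) in summaries.items():
        call = call_differential(cs, ts, p_values[(acc, pep, cys)], config,
                                 q_value=q_map[(acc, pep, cys)])
        calls.append(call)
        rows.append(
            {
                "accession": acc,
                "peptide": pep,
                "cys_positions": cys,
                "n_case_subjects": cs.n_subjects,
                "n_control_subjects": ts.n_subjects,
                "case_mean": cs.group_mean,
                "control_mean": ts.group_mean,
                "ratio_of_ratios": call.ratio_of_ratios,
                "p_value": call.p_value,
                "q_value": call.q_value if call.q_value is not None else float("nan"),
                "passes_fold": call.passes_fold,
                "passes_p": call.passes_p,
                "significant": call.significant,
            }
        )
    peptide_df = _calls_to_frame(rows)
    if len(peptide_df):
        peptide_df = peptide_df.sort_values(
            ["accession", "peptide", "cys_positions"], kind="mergesort"
        ).reset_index(drop=True)

    protein_rows = [
        {
            "accession": pc.accession,
            "n_peptides_total": pc.n_peptides_total,
            "n_peptides_significant": pc.n_peptides_significant,
            "significant": pc.significant,
            "best_ratio_of_ratios": pc.best_ratio_of_ratios,
            "best_p_value": pc.best_p_value,
        }
        for pc in rollup_to_proteins(calls)
    ]
    protein_df = pd.DataFrame(
        protein_rows,
        columns=[
            "accession",
            "n_peptides_total",
            "n_peptides_significant",
            "significant",
            "best_ratio_of_ratios",
            "best_p_value",
        ],
    )

    site_df = None
    unmapped: list[str] = []
    if proteins is not None:
        site_rows = []
        for row in peptide_df.itertuples(index=False):
            protein = proteins.get(row.accession)
            if protein is None:
                if row.accession not in unmapped:
                    unmapped.append(row.accession)
                continue
            cys_positions = (
                tuple(int(x) for x in row.cys_positions.split(";"))
                if row.cys_positions
                else ()
            )
            try:
                mapping = map_peptide_to_protein(row.peptide, cys_positions, protein)
            except UnmappedPeptideError:
                if row.accession not in unmapped:
                    unmapped.append(row.accession)
                continue
            for site in mapping.sites:
                site_rows.append(
                    {
                        "accession": site.accession,
                        "position": site.position,
                        "peptide": row.peptide,
                        "ambiguous": mapping.ambiguous,
                        "ratio_of_ratios": row.ratio_of_ratios,
                        "p_value": row.p_value,
                        "significant": row.significant,
                    }
                )
        site_df = pd.DataFrame(
            site_rows,
            columns=[
                "accession",
                "position",
                "peptide",
                "ambiguous",
                "ratio_of_ratios",
                "p_value",
                "significant",
            ],
        )
        if len(site_df):
            site_df = site_df.sort_values(
                ["accession", "position", "peptide"], kind="mergesort"
            ).reset_index(drop=True)

    return QuantResult(
        peptide_calls=peptide_df,
        protein_calls=protein_df,
        site_calls=site_df,
        filter_log=flog,
        n_excluded_insufficient=n_excluded,
        excluded_keys=excluded,
        unmapped_accessions=unmapped,
    )
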