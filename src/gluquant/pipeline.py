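"""Orchestration: simulate → quantify → overlap → report.

Provides the two-arm study driver (e.g. disease vs control alongside a
chemically perturbed vs vehicle arm, with a Venn of significant protein
sets between arms) and the recovery benchmark that scores the pipeline
against planted ground truth (sensitivity and empirical false-discovery
proportion over cysteine sites).

All randomness flows from a single mandatory seed; per-stage substreams are
derived deterministically, so a report is fully determined by inputs and
configuration.  Results files never mix with logs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import VennCounts, overlap_sets
from .io_formats import (
    DEFAULT_DIALECT,
    PeptideMeasurement,
    ProteinRecord,
    write_results_table,
)
from .quant import QuantConfig, QuantResult, run_differential
from .synthetic import SimConfig, SimOutput, simulate

logger = logging.getLogger("gluquant")


@dataclass
class ArmSummary:
    """Stage counts for one comparison arm."""

    name: str
    n_rows_read: int
    n_rejected_parse: int
    filter_log: dict[str, int]
    n_excluded_insufficient: int
    n_peptides_tested: int
    n_peptides_significant: int
    n_proteins_total: int
    n_proteins_significant: int


@dataclass
class RunReport:
    """Machine-readable run summary: config echo, stage counts, Venn, recovery."""

    seed: int | None
    quant_config: dict
    sim_config: dict | None = None
    arms: list[dict] = field(default_factory=list)
    venn: dict | None = None
    recovery: dict | None = None

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "quant_config": self.quant_config,
            "sim_config": self.sim_config,
            "arms": self.arms,
            "venn": self.venn,
            "recovery": self.recovery,
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _config_echo(config) -> dict:
    return {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in asdict(config).items()
    }


def _quantify_arm(
    name: str,
    measurements: Sequence[PeptideMeasurement],
    n_rejected_parse: int,
    config: QuantConfig,
    proteins: Mapping[str, ProteinRecord] | None,
) -> tuple[QuantResult, ArmSummary]:
    result = run_differential(measurements, config, proteins=proteins)
    pep = result.peptide_calls
    prot = result.protein_calls
    summary = ArmSummary(
        name=name,
        n_rows_read=len(measurements) + n_rejected_parse,
        n_rejected_parse=n_rejected_parse,
        filter_log=result.filter_log.as_dict(),
        n_excluded_insufficient=result.n_excluded_insufficient,
        n_peptides_tested=len(pep),
        n_peptides_significant=int(pep["significant"].sum()) if len(pep) else 0,
        n_proteins_total=len(prot),
        n_proteins_significant=int(prot["significant"].sum()) if len(prot) else 0,
    )
    logger.info(
        "arm %s: %d rows read, %d retained after filters, %d peptides tested, "
        "%d significant peptides, %d/%d significant proteins",
        name,
        summary.n_rows_read,
        result.filter_log.n_retained,
        summary.n_peptides_tested,
        summary.n_peptides_significant,
        summary.n_proteins_significant,
        summary.n_proteins_total,
    )
    return result, summary


def run_two_arm(
    arm_measurements: Mapping[str, Sequence[PeptideMeasurement]],
    config: QuantConfig = QuantConfig(),
    proteins: Mapping[str, ProteinRecord] | None = None,
    out_dir: str | Path | None = None,
    n_rejected_parse: Mapping[str, int] | None = None,
    seed: int | None = None,
) -> tuple[dict[str, QuantResult], RunReport]:
    """Run the differential analysis for two comparison arms and overlap them.

    ``arm_measurements`` maps arm name → parsed peptide measurements for that
    arm (each arm's table carries both case and control rows).  Writes
    per-arm peptide/protein/site tables and a JSON report when ``out_dir``
    is given.  An arm in which no peptide survives the filters is an error
    (the stage counts are attached to the exception message).
    """
    if len(arm_measurements) != 2:
        raise ValueError("run_two_arm expects exactly two arms")
    rejected = n_rejected_parse or {}
    results: dict[str, QuantResult] = {}
    summaries: list[ArmSummary] = []
    for name in arm_measurements:
        result, summary = _quantify_arm(
            name, arm_measurements[name], rejected.get(name, 0), config, proteins
        )
        if summary.n_peptides_tested == 0:
            raise ValueError(
                f"arm {name!r}: no peptides survive filtering; stage counts: "
                f"{summary.filter_log}, "
                f"insufficient-subject exclusions: {summary.n_excluded_insufficient}"
            )
        results[name] = result
        summaries.append(summary)

    name_a, name_b = list(arm_measurements)
    sig_a = _significant_proteins(results[name_a])
    sig_b = _significant_proteins(results[name_b])
    if sig_a:
        venn = overlap_sets(sig_a, sig_b)
        venn_dict = {
            "arm_a": name_a,
            "arm_b": name_b,
            "only_a": venn.only_a,
            "only_b": venn.only_b,
            "shared": venn.shared,
            "shared_fraction_a": venn.shared_fraction_a,
        }
    else:
        venn_dict = {
            "arm_a": name_a,
            "arm_b": name_b,
            "only_a": 0,
            "only_b": len(sig_b),
            "shared": 0,
            "shared_fraction_a": None,
        }

    report = RunReport(
        seed=seed,
        quant_config=_config_echo(config),
        arms=[asdict(s) for s in summaries],
        venn=venn_dict,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, result in results.items():
            write_results_table(result.peptide_calls, out_dir / f"{name}_peptides.tsv")
            if len(result.protein_calls):
                write_results_table(
                    result.protein_calls, out_dir / f"{name}_proteins.tsv"
                )
            if result.site_calls is not None and len(result.site_calls):
                write_results_table(result.site_calls, out_dir / f"{name}_sites.tsv")
        report.write(out_dir / "report.json")
    return results, report


def _significant_proteins(result: QuantResult) -> set[str]:
    df = result.protein_calls
    if not len(df):
        return set()
    return set(df.loc[df["significant"], "accession"])


# ---------------------------------------------------------------------------
# Recovery benchmark against planted ground truth
# ---------------------------------------------------------------------------

@dataclass
class RecoveryMetrics:
    """Site-level recovery of planted effects.

    ``sensitivity`` = TP/(TP+FN) over planted sites (None when nothing was
    planted); ``fdp`` = FP/(FP+TP) over called sites (0 when nothing called).
    """

    n_sites_truth: int
    n_sites_planted: int
    n_sites_called: int
    tp: int
    fp: int
    fn: int
    sensitivity: float | None
    fdp: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def score_recovery(site_calls: pd.DataFrame, truth: pd.DataFrame) -> RecoveryMetrics:
    """Join site-level calls to ground truth by (accession, position).

    Ambiguously mapped sites (peptide occurring more than once in the
    protein) are excluded from scoring: their attribution is unknown, so
    neither a hit nor a miss can be credited to a specific site.
    """
    if len(site_calls):
        ambiguous_sites = set(
            zip(
                site_calls.loc[site_calls["ambiguous"].astype(bool), "accession"],
                site_calls.loc[site_calls["ambiguous"].astype(bool), "position"],
            )
        )
        unambiguous = site_calls.loc[~site_calls["ambiguous"].astype(bool)]
        called = set(
            zip(
                unambiguous.loc[unambiguous["significant"], "accession"],
                unambiguous.loc[unambiguous["significant"], "position"],
            )
        )
    else:
        ambiguous_sites = set()
        called = set()
    truth_sites = (
        set(zip(truth["accession"], truth["position"])) - ambiguous_sites
    )
    planted = set(
        zip(
            truth.loc[truth["is_differential"], "accession"],
            truth.loc[truth["is_differential"], "position"],
        )
    ) - ambiguous_sites
    called &= truth_sites  # score only sites with known truth
    tp = len(called & planted)
    fp = len(called - planted)
    fn = len(planted - called)
    return RecoveryMetrics(
        n_sites_truth=len(truth_sites),
        n_sites_planted=len(planted),
        n_sites_called=len(called),
        tp=tp,
        fp=fp,
        fn=fn,
        sensitivity=(tp / (tp + fn)) if planted else None,
        fdp=(fp / (fp + tp)) if (fp + tp) else 0.0,
    )


def run_recovery_benchmark(
    sim_config: SimConfig,
    quant_config: QuantConfig = QuantConfig(),
    out_dir: str | Path | None = None,
) -> tuple[SimOutput, QuantResult, RunReport]:
    """Simulate, quantify, and score recovery of planted effects.

    Raises when the configuration requests planted effects but the simulated
    proteome yields none (degenerate cysteine frequency or tiny proteome).
    """
    sim = simulate(sim_config)
    if sim_config.fraction_differential > 0 and (
        len(sim.truth) == 0 or not sim.truth["is_differential"].any()
    ):
        raise ValueError(
            "no planted sites despite fraction_differential > 0; "
            "increase n_proteins or cys_frequency"
        )
    measurements = _frame_to_measurements(sim.table)
    result = run_differential(measurements, quant_config, proteins=sim.proteome)
    metrics = score_recovery(result.site_calls, sim.truth)
    logger.info(
        "recovery: sensitivity=%s fdp=%.4f (tp=%d fp=%d fn=%d)",
        f"{metrics.sensitivity:.4f}" if metrics.sensitivity is not None else "n/a",
        metrics.fdp,
        metrics.tp,
        metrics.fp,
        metrics.fn,
    )
    pep = result.peptide_calls
    report = RunReport(
        seed=sim_config.seed,
        quant_config=_config_echo(quant_config),
        sim_config=_config_echo(sim_config),
        arms=[
            {
                "name": "benchmark",
                "n_rows_read": len(sim.table),
                "n_rejected_parse": 0,
                "filter_log": result.filter_log.as_dict(),
                "n_excluded_insufficient": result.n_excluded_insufficient,
                "n_peptides_tested": len(pep),
                "n_peptides_significant": int(pep["significant"].sum())
                if len(pep)
                else 0,
                "n_proteins_total": len(result.protein_calls),
                "n_proteins_significant": int(
                    result.protein_calls["significant"].sum()
                )
                if len(result.protein_calls)
                else 0,
            }
        ],
        recovery=metrics.as_dict(),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_results_table(result.peptide_calls, out_dir / "benchmark_peptides.tsv")
        if result.site_calls is not None and len(result.site_calls):
            write_results_table(result.site_calls, out_dir / "benchmark_sites.tsv")
        report.write(out_dir / "report.json")
    return sim, result, report


def _frame_to_measurements(table: pd.DataFrame) -> list[PeptideMeasurement]:
    """Convert a dialect-conformant frame into measurement objects."""
    col = DEFAULT_DIALECT.column_map
    out = []
    for row in table.itertuples(index=False):
        rec = dict(zip(table.columns, row))
        cys = str(rec[col["cys_positions"]])
        out.append(
            PeptideMeasurement(
                sample_id=str(rec[col["sample_id"]]),
                subject_id=str(rec[col["subject_id"]]),
                group=str(rec[col["group"]]),
                replicate_index=int(rec[col["replicate"]]),
                accession=str(rec[col["accession"]]),
                peptide_sequence=str(rec[col["peptide"]]),
                peptide_cys_positions=tuple(
                    int(x) for x in cys.split(";") if x.strip()
                ),
                confidence_pct=float(rec[col["confidence"]]),
                h_to_l=float(rec[col["h_to_l"]]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Figure export (basic volcano / Venn summary, nothing publication-grade)
# ---------------------------------------------------------------------------

def plot_volcano(peptide_calls: pd.DataFrame, path: str | Path) -> None:
    """Scatter of log2 RoR vs −log10 p, significant peptides highlighted."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = peptide_calls
    fig, ax = plt.subplots(figsize=(5, 4))
    x = np.log2(df["ratio_of_ratios"])
    y = -np.log10(df["p_value"])
    sig = df["significant"].astype(bool)
    ax.scatter(x[~sig], y[~sig], s=6, c="grey", alpha=0.5, label="not significant")
    ax.scatter(x[sig], y[sig], s=8, c="crimson", label="significant")
    ax.set_xlabel("log2 ratio-of-ratios (case/control)")
    ax.set_ylabel("-log10 p (Mann-Whitney)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_venn(venn: VennCounts, labels: tuple[str, str], path: str | Path) -> None:
    """Two-circle Venn rendered from precomputed partition counts."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.add_patch(Circle((0.38, 0.5), 0.32, alpha=0.4, color="steelblue"))
    ax.add_patch(Circle((0.62, 0.5), 0.32, alpha=0.4, color="darkorange"))
    ax.text(0.25, 0.5, str(venn.only_a), ha="center", fontsize=14)
    ax.text(0.5, 0.5, str(venn.shared), ha="center", fontsize=14)
    ax.text(0.75, 0.5, str(venn.only_b), ha="center", fontsize=14)
    ax.text(0.3, 0.88, labels[0], ha="center")
    ax.text(0.7, 0.88, labels[1], ha="center")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.axis("off")
    fig.savefig(path, dpi=150)
    plt.close(fig)
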