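"""Synthetic ICAT glutathionylation data with planted ground truth.

Simulates the generative process behind a cleavable-ICAT redox experiment:
a random proteome is digested with trypsin in silico; each cysteine site
carries a glutathionylation occupancy θ per condition; the observable for a
Cys peptide is the heavy:light ratio r = θ/(1−θ) (heavy labels Grx-released
glutathionylated thiols, light labels reduced thiols), corrupted by
multiplicative lognormal noise and missing-completely-at-random dropout.
A configurable fraction of sites receives a planted case/control effect
with a target ratio-of-ratios, recorded in a ground-truth sidecar so that
recovery (sensitivity, false-discovery proportion) can be scored.

Effects are planted per *site cluster* — all cysteines sharing a tryptic
peptide receive the same occupancy and differential status — because a
peptide carries a single H:L value, so sites within one peptide are not
separately observable.  With the default of zero missed cleavages, clusters
coincide with tryptic peptides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CASE,
    CONTROL,
    DEFAULT_DIALECT,
    LOGICAL_COLUMNS,
    ProteinRecord,
    SiteKey,
)

# Amino-acid background (frequencies loosely following the vertebrate
# proteome, renormalized): K+R ≈ 11% so tryptic peptides average ~9 residues.
_AA_BACKGROUND = {
    "A": 0.074, "D": 0.054, "E": 0.068, "F": 0.040, "G": 0.074,
    "H": 0.026, "I": 0.048, "K": 0.058, "L": 0.090, "M": 0.022,
    "N": 0.044, "P": 0.050, "Q": 0.042, "R": 0.052, "S": 0.081,
    "T": 0.062, "V": 0.060, "W": 0.013, "Y": 0.033,
}


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters of the simulator.

    The subject design copies the original case/control experiment
    (11 cases vs 7 controls, each measured in technical duplicate) so that
    recovery experiments run in the same power regime.  ``noise_cv`` is the
    coefficient of variation of the multiplicative lognormal error on an
    observed H:L ratio; ``baseline_occupancy`` are Beta(a, b) parameters for
    control-condition occupancies.
    """

    seed: int
    n_proteins: int = 80
    protein_length_range: tuple[int, int] = (200, 400)
    cys_frequency: float = 0.03
    n_case_subjects: int = 11
    n_control_subjects: int = 7
    n_technical_replicates: int = 2
    baseline_occupancy: tuple[float, float] = (2.0, 8.0)
    fraction_differential: float = 0.10
    effect_ratio: float = 2.0
    noise_cv: float = 0.20
    missing_rate: float = 0.10
    confidence_high_fraction: float = 0.90
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        for p in (self.cys_frequency, self.fraction_differential,
                  self.missing_rate, self.confidence_high_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.effect_ratio < 1.0:
            raise ValueError("effect_ratio must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if self.n_technical_replicates < 1:
            raise ValueError("need at least one technical replicate")
        if not (0 <= self.missed_cleavages <= 2):
            raise ValueError("missed_cleavages must be 0-2")
        if self.protein_length_range[0] < 2:
            raise ValueError("proteins must have length >= 2")


@dataclass
class SimOutput:
    """Everything one simulation emits."""

    proteome: dict[str, ProteinRecord]
    table: pd.DataFrame  # peptide table in the io_formats dialect
    truth: pd.DataFrame  # per-site ground truth sidecar
    config: SimConfig


# ---------------------------------------------------------------------------
# Proteome generation
# ---------------------------------------------------------------------------

def generate_proteome(config: SimConfig) -> dict[str, ProteinRecord]:
    """Generate a random proteome, reproducible per seed.

    Sequences are drawn from a fixed amino-acid background with the cysteine
    frequency overridden by ``cys_frequency``; every protein is guaranteed at
    least one K/R so trypsin produces more than a single fragment.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    aas = sorted(_AA_BACKGROUND)
    base = np.array([_AA_BACKGROUND[a] for a in aas])
    base = base / base.sum() * (1.0 - config.cys_frequency)
    letters = np.array(aas + ["C"])
    probs = np.append(base, config.cys_frequency)

    lo, hi = config.protein_length_range
    width = len(str(config.n_proteins))
    proteome: dict[str, ProteinRecord] = {}
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(letters, size=length, p=probs)
        if not np.isin(seq, ["K", "R"]).any():
            seq[int(rng.integers(0, length))] = "K"
        acc = f"SYNP{i + 1:0{width}d}"
        proteome[acc] = ProteinRecord(
            accession=acc,
            description=f"{acc} synthetic protein",
            sequence="".join(seq),
        )
    return proteome


# ---------------------------------------------------------------------------
# In-silico trypsin digestion
# ---------------------------------------------------------------------------

def tryptic_digest(sequence: str, missed_cleavages: int = 0) -> list[str]:
    """Digest a sequence with trypsin: cleave after K/R unless followed by P.

    With ``missed_cleavages`` = 0 the returned peptides concatenate back to
    the input sequence; higher settings additionally emit peptides spanning
    up to that many skipped cleavage sites (fully cleaved fragments first).
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    fragments: list[str] = []
    start = 0
    for i, aa in enumerate(sequence):
        at_end = i == len(sequence) - 1
        cleave = aa in "KR" and not at_end and sequence[i + 1] != "P"
        if cleave or at_end:
            fragments.append(sequence[start : i + 1])
            start = i + 1
    if missed_cleavages == 0:
        return fragments
    peptides = list(fragments)
    for span in range(2, missed_cleavages + 2):
        for j in range(len(fragments) - span + 1):
            peptides.append("".join(fragments[j : j + span]))
    return peptides


def cys_peptides(
    protein: ProteinRecord, missed_cleavages: int = 0
) -> list[tuple[str, tuple[int, ...], tuple[int, ...]]]:
    """Unique cysteine-containing tryptic peptides of one protein.

    Returns ``(peptide, peptide_cys_positions, protein_cys_positions)``
    triples, 1-based on both scales, ordered by position in the protein.
    Duplicate peptide sequences within a protein are emitted once (their
    site mapping is ambiguous and resolved downstream).
    """
    fragments = tryptic_digest(protein.sequence, 0)
    spans: list[tuple[int, str]] = []
    pos = 0
    for frag in fragments:
        spans.append((pos, frag))
        pos += len(frag)
    if missed_cleavages > 0:
        for span in range(2, missed_cleavages + 2):
            for j in range(len(fragments) - span + 1):
                start = spans[j][0]
                spans.append((start, "".join(fragments[j : j + span])))
    out = []
    seen: set[str] = set()
    for start, pep in sorted(spans):
        if "C" not in pep or pep in seen:
            continue
        seen.add(pep)
        pep_cys = tuple(i + 1 for i, aa in enumerate(pep) if aa == "C")
        prot_cys = tuple(start + i for i in pep_cys)
        out.append((pep, pep_cys, prot_cys))
    return out


# ---------------------------------------------------------------------------
# Ground truth: occupancies and planted effects
# ---------------------------------------------------------------------------

def plant_effects(
    site_clusters: Sequence[Sequence[SiteKey]],
    config: SimConfig,
) -> pd.DataFrame:
    """Assign occupancies and plant differential effects on site clusters.

    Each cluster (the cysteines of one tryptic peptide) draws a control
    occupancy θ_control ~ Beta(a, b); a ``fraction_differential`` subset of
    clusters is planted with θ_case solved so that the occupancy odds ratio
    equals ``effect_ratio``: with ρ = θ_control/(1−θ_control) and
    e = effect_ratio, θ_case = e·ρ / (1 + e·ρ).  Unplanted clusters keep
    θ_case = θ_control.

    Returns one row per site with columns accession, position, theta_control,
    theta_case, is_differential, expected_ratio_of_ratios, cluster_id.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    n = len(site_clusters)
    a, b = config.baseline_occupancy
    theta_control = rng.beta(a, b, size=n)
    n_diff = int(round(config.fraction_differential * n))
    diff_idx = set(rng.choice(n, size=n_diff, replace=False).tolist()) if n_diff else set()

    rows = []
    for ci, cluster in enumerate(site_clusters):
        tc = float(theta_control[ci])
        is_diff = ci in diff_idx and config.effect_ratio != 1.0
        if is_diff:
            rho = tc / (1.0 - tc)
            tcase = config.effect_ratio * rho / (1.0 + config.effect_ratio * rho)
            while tcase >= 1.0:  # unreachable for finite effect_ratio; guard
                tc = float(rng.beta(a, b))
                rho = tc / (1.0 - tc)
                tcase = config.effect_ratio * rho / (1.0 + config.effect_ratio * rho)
            expected_ror = config.effect_ratio
        else:
            tcase = tc
            expected_ror = 1.0
        for site in cluster:
            rows.append(
                {
                    "accession": site.accession,
                    "position": site.position,
                    "theta_control": tc,
                    "theta_case": tcase,
                    "is_differential": is_diff,
                    "expected_ratio_of_ratios": expected_ror,
                    "cluster_id": ci,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "accession",
            "position",
            "theta_control",
            "theta_case",
            "is_differential",
            "expected_ratio_of_ratios",
            "cluster_id",
        ],
    )


# ---------------------------------------------------------------------------
# Peptide-table simulation
# ---------------------------------------------------------------------------

def _subject_ids(config: SimConfig) -> list[tuple[str, str]]:
    """(subject_id, group) pairs; cases first, deterministic order."""
    ids = [(f"CASE{i + 1:02d}", CASE) for i in range(config.n_case_subjects)]
    ids += [(f"CTRL{i + 1:02d}", CONTROL) for i in range(config.n_control_subjects)]
    return ids


def simulate_peptide_table(
    proteome: dict[str, ProteinRecord],
    truth: pd.DataFrame,
    config: SimConfig,
) -> pd.DataFrame:
    """Emit a pipeline-ready peptide table from a proteome and ground truth.

    For every subject, technical replicate, and Cys tryptic peptide the
    noise-free ratio is r = θ̄/(1−θ̄) with θ̄ the mean occupancy of the
    peptide's sites in that subject's condition; the observation is
    r·exp(ε_H − ε_L) with iid normal channel errors sized to the configured
    ratio CV, then thinned by MCAR dropout.  Identification confidence is a
    mixture: ``confidence_high_fraction`` of observations draw U(95, 100),
    the rest U(50, 95).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    theta_by_site: dict[tuple[str, int], tuple[float, float]] = {
        (r.accession, r.position): (r.theta_control, r.theta_case)
        for r in truth.itertuples(index=False)
    }
    # sigma of each channel's log error: Var(eps_H - eps_L) = 2 sigma^2 and
    # CV of exp(N(0, s^2)) = sqrt(exp(s^2) - 1)  =>  s^2 = log(1 + cv^2)
    s2 = math.log(1.0 + config.noise_cv**2)
    channel_sigma = math.sqrt(s2 / 2.0)

    subjects = _subject_ids(config)
    col = DEFAULT_DIALECT.column_map
    rows = []
    for acc in sorted(proteome):
        for pep, pep_cys, prot_cys in cys_peptides(
            proteome[acc], config.missed_cleavages
        ):
            thetas = [theta_by_site[(acc, p)] for p in prot_cys]
            theta_ctrl = float(np.mean([t[0] for t in thetas]))
            theta_case = float(np.mean([t[1] for t in thetas]))
            r_by_group = {
                CONTROL: theta_ctrl / (1.0 - theta_ctrl),
                CASE: theta_case / (1.0 - theta_case),
            }
            for subject_id, group in subjects:
                for rep in range(1, config.n_technical_replicates + 1):
                    # draw the full noise vector before dropout so the
                    # retained stream is identical across missing rates
                    eps_h = rng.normal(0.0, channel_sigma) if channel_sigma else 0.0
                    eps_l = rng.normal(0.0, channel_sigma) if channel_sigma else 0.0
                    dropped = (
                        config.missing_rate > 0
                        and rng.random() < config.missing_rate
                    )
                    if config.confidence_high_fraction >= 1.0:
                        conf = rng.uniform(95.0, 100.0)
                    elif rng.random() < config.confidence_high_fraction:
                        conf = rng.uniform(95.0, 100.0)
                    else:
                        conf = rng.uniform(50.0, 95.0)
                    if dropped:
                        continue
                    h_to_l = r_by_group[group] * math.exp(eps_h - eps_l)
                    rows.append(
                        {
                            col["sample_id"]: f"{subject_id}_R{rep}",
                            col["subject_id"]: subject_id,
                            col["group"]: group,
                            col["replicate"]: rep,
                            col["accession"]: acc,
                            col["peptide"]: pep,
                            col["cys_positions"]: ";".join(str(p) for p in pep_cys),
                            col["confidence"]: round(conf, 4),
                            col["h_to_l"]: h_to_l,
                        }
                    )
    return pd.DataFrame(rows, columns=[col[c] for c in LOGICAL_COLUMNS])


def simulate(config: SimConfig) -> SimOutput:
    """Full simulation: proteome → site clusters → truth → peptide table."""
    proteome = generate_proteome(config)
    clusters: list[list[SiteKey]] = []
    for acc in sorted(proteome):
        for _pep, _pc, prot_cys in cys_peptides(proteome[acc], 0):
            clusters.append([SiteKey(acc, p) for p in prot_cys])
    if config.cys_frequency == 0.0 and not clusters:
        truth = pd.DataFrame(
            columns=[
                "accession",
                "position",
                "theta_control",
                "theta_case",
                "is_differential",
                "expected_ratio_of_ratios",
                "cluster_id",
            ]
        )
    else:
        truth = plant_effects(clusters, config)
    table = simulate_peptide_table(proteome, truth, config)
    return SimOutput(proteome=proteome, table=table, truth=truth, config=config)


def write_sim_output(out: SimOutput, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA proteome, TSV peptide table, TSV truth sidecar, JSON echo."""
    import json

    from .io_formats import write_fasta, write_results_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteome": out_dir / "proteome.fasta",
        "table": out_dir / "peptide_table.tsv",
        "truth": out_dir / "ground_truth.tsv",
        "config": out_dir / "sim_config.json",
    }
    write_fasta(out.proteome.values(), paths["proteome"])
    out.table.to_csv(
        paths["table"], sep="\t", index=False, float_format="%.12g",
        lineterminator="\n",
    )
    write_results_table(out.truth, paths["truth"])
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in out.config.__dict__.items()}
    paths["config"].write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
    return paths
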