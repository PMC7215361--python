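"""Set overlap and hypergeometric over-representation analysis.

A transparent stand-in for proprietary pathway tools: significant protein
sets from two comparisons are intersected (Venn), and hit sets are tested
for over-representation in user-supplied annotation sets (GMT format) with
an upper-tail hypergeometric test and Benjamini–Hochberg correction.
Joint proteo-metabolomic enrichment pools the two feature universes, with
identifiers tagged by kind to avoid collisions.

The default enrichment universe should be all *quantified* features, not
all significant ones: conditioning on detectability avoids abundance bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .quant import benjamini_hochberg

PROTEIN = "protein"
METABOLITE = "metabolite"


@dataclass(frozen=True)
class AnnotationSet:
    """One pathway/term: identifier, label, member feature identifiers."""

    set_id: str
    label: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"annotation set {self.set_id!r} has no members")


@dataclass(frozen=True)
class VennCounts:
    """Two-set partition counts and the shared fraction of set A."""

    only_a: int
    only_b: int
    shared: int
    shared_fraction_a: float  # shared / |A|


def overlap_sets(set_a: Iterable[str], set_b: Iterable[str]) -> VennCounts:
    """Exact two-set partition; ``shared_fraction_a`` = |A∩B| / |A|."""
    a, b = set(set_a), set(set_b)
    if not a:
        raise ValueError("set_a is empty: shared fraction undefined")
    shared = len(a & b)
    return VennCounts(
        only_a=len(a - b),
        only_b=len(b - a),
        shared=shared,
        shared_fraction_a=shared / len(a),
    )


def read_gmt(path: str | Path) -> list[AnnotationSet]:
    """Read a GMT file: set_id <tab> label <tab> member1 <tab> member2 ..."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line has fewer than 3 fields: {line!r}")
        sets.append(
            AnnotationSet(
                set_id=parts[0],
                label=parts[1],
                members=frozenset(p for p in parts[2:] if p),
            )
        )
    if not sets:
        raise ValueError(f"no annotation sets found in {path}")
    return sets


_RESULT_COLUMNS = [
    "set_id",
    "label",
    "k_overlap",
    "n_hits",
    "K_setsize",
    "N_universe",
    "p_value",
    "q_value",
]


def hypergeometric_enrichment(
    hits: Iterable[str],
    annotation_sets: Sequence[AnnotationSet],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``hits`` per set.

    Each annotation set is intersected with the universe before testing;
    p = P(X ≥ k) for X ~ Hypergeometric(N=|universe|, K=|set∩universe|,
    n=|hits|), with Benjamini–Hochberg q-values across sets.  Results are
    sorted by p then set_id.  Hits outside the universe are an error.
    """
    hit_set = set(hits)
    uni = set(universe)
    offenders = sorted(hit_set - uni)
    if offenders:
        raise ValueError(
            "hits not contained in universe: " + ", ".join(offenders[:10])
        )
    N, n = len(uni), len(hit_set)
    rows = []
    for aset in annotation_sets:
        members = aset.members & uni
        K = len(members)
        k = len(members & hit_set)
        # survival function at k-1 gives P(X >= k); k = 0 -> p = 1 exactly
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append(
            {
                "set_id": aset.set_id,
                "label": aset.label,
                "k_overlap": k,
                "n_hits": n,
                "K_setsize": K,
                "N_universe": N,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows, columns=[c for c in _RESULT_COLUMNS if c != "q_value"])
    out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy()) if len(out) else []
    return out.sort_values(["p_value", "set_id"], kind="mergesort").reset_index(
        drop=True
    )


def _tag(kind: str, identifier: str) -> str:
    return f"{kind}:{identifier}"


def joint_pathway_enrichment(
    protein_hits: Iterable[str],
    metabolite_hits: Iterable[str],
    pathway_sets: Sequence[AnnotationSet],
    protein_universe: Iterable[str],
    metabolite_universe: Iterable[str],
) -> pd.DataFrame:
    """Joint proteo-metabolomic enrichment over a pooled, kind-tagged universe.

    Pathway members are resolved against both universes and tagged
    ``protein:``/``metabolite:``; an untagged identifier present in both
    universes is ambiguous and raises.  A single hypergeometric test per
    pathway runs on the pooled counts; per-kind overlap counts are reported
    alongside.  Pathways containing only protein members reduce exactly to
    :func:`hypergeometric_enrichment`.
    """
    prot_uni, met_uni = set(protein_universe), set(metabolite_universe)
    prot_hits, met_hits = set(protein_hits), set(metabolite_hits)
    if not prot_hits <= prot_uni:
        raise ValueError(
            "protein hits outside universe: "
            + ", ".join(sorted(prot_hits - prot_uni)[:10])
        )
    if not met_hits <= met_uni:
        raise ValueError(
            "metabolite hits outside universe: "
            + ", ".join(sorted(met_hits - met_uni)[:10])
        )

    pooled_universe = {_tag(PROTEIN, x) for x in prot_uni} | {
        _tag(METABOLITE, x) for x in met_uni
    }
    pooled_hits = {_tag(PROTEIN, x) for x in prot_hits} | {
        _tag(METABOLITE, x) for x in met_hits
    }

    def resolve(member: str) -> str | None:
        if member.startswith((PROTEIN + ":", METABOLITE + ":")):
            return member if member in pooled_universe else None
        in_p, in_m = member in prot_uni, member in met_uni
        if in_p and in_m:
            raise ValueError(
                f"identifier {member!r} present in both universes; tag it "
                f"'{PROTEIN}:{member}' or '{METABOLITE}:{member}'"
            )
        if in_p:
            return _tag(PROTEIN, member)
        if in_m:
            return _tag(METABOLITE, member)
        return None

    tagged_sets = []
    for aset in pathway_sets:
        resolved = {r for m in aset.members if (r := resolve(m)) is not None}
        tagged_sets.append((aset, resolved))

    N, n = len(pooled_universe), len(pooled_hits)
    rows = []
    for aset, members in tagged_sets:
        K = len(members)
        overlap = members & pooled_hits
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append(
            {
                "set_id": aset.set_id,
                "label": aset.label,
                "k_overlap": k,
                "k_protein": sum(1 for x in overlap if x.startswith(PROTEIN + ":")),
                "k_metabolite": sum(
                    1 for x in overlap if x.startswith(METABOLITE + ":")
                ),
                "n_hits": n,
                "K_setsize": K,
                "N_universe": N,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "set_id",
            "label",
            "k_overlap",
            "k_protein",
            "k_metabolite",
            "n_hits",
            "K_setsize",
            "N_universe",
            "p_value",
        ],
    )
    out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy()) if len(out) else []
    return out.sort_values(["p_value", "set_id"], kind="mergesort").reset_index(
        drop=True
    )
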