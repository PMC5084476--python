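"""Comparative screens for C4-associated regulation.

Two species sets anchor the screen: C3 comparators (e.g. a C3 panicoid and a
C3 BEP grass) and C4 species from independent C4 origins (e.g. two
Andropogoneae and one Paniceae).  A transcription factor whose leaf-gradient
profile diverges from the C3 consensus in one or more C4 species — after
membership in photosynthesis co-expression clusters and a minimum-expression
cut — is a candidate C4 regulator, and the subset of C4 species showing the
divergence classifies it as reference-specific, clade-shared, or pan-C4.

Profiles are compared only after per-gene max-normalization: absolute FPKM
is never compared across species.  Divergence of two normalized 4-point
shapes defaults to one minus their Pearson correlation; near-flat profiles
carry no usable shape signal, so whenever either profile varies by less than
``flat_tol`` (coefficient of variation) the scale-bounded Euclidean distance
is used instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidSpecError

PAN_C4 = "pan-C4"
NONE = "none"
REFERENCE_SPECIFIC = "reference-specific"


@dataclass(frozen=True)
class Species:
    """A species in the comparison: photosynthetic type and clade tag."""

    label: str
    ptype: str  # 'C3' | 'C4'
    clade: str

    def __post_init__(self):
        if self.ptype not in ("C3", "C4"):
            raise InvalidSpecError("ptype must be 'C3' or 'C4'")


@dataclass
class ScreenConfig:
    """Thresholds for induction calls and the three-stage TF filter."""

    cluster_tf_ids: tuple = ()
    mean_fpkm_min: float = 4.0
    divergence_metric: str = "one-minus-pearson"
    divergence_tau: float = 0.33
    c3_consistency_tau: float = 0.33
    min_effect: float = 0.28
    tip_fold_min: float = 4.0
    tip_fpkm_min: float = 50.0
    flat_tol: float = 0.3

    def __post_init__(self):
        for name in (
            "mean_fpkm_min", "divergence_tau", "c3_consistency_tau",
            "tip_fold_min", "tip_fpkm_min",
        ):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be positive")
        if self.divergence_metric not in (
            "one-minus-pearson", "euclidean-on-normalized"
        ):
            raise InvalidSpecError(
                f"unknown divergence metric {self.divergence_metric!r}"
            )


@dataclass
class TFCandidate:
    """A regulator surviving the three-stage filter."""

    gene: str
    orthologs: dict
    divergence_flags: dict
    scores: dict
    non_comparable: frozenset
    category: str = NONE


# ---------------------------------------------------------------------------
# induction of the core carbon-shuttle enzymes
# ---------------------------------------------------------------------------

def assess_induction(profile, config: ScreenConfig | None = None):
    """C4-style transcriptional induction call for a 4-point mean profile.

    TRUE requires a high tip value, a tip/base fold of at least
    ``tip_fold_min``, and a profile non-decreasing from stage 2 onward
    (10 % tolerance).  High-but-flat expression therefore does not qualify.
    """
    config = config or ScreenConfig()
    p = np.asarray(profile, dtype=float)
    if p.shape != (4,):
        raise InvalidSpecError("profile must have exactly 4 stages")
    tip, base = p[-1], p[0]
    fold = np.inf if base == 0 else tip / base
    nondecreasing = all(p[i + 1] >= 0.9 * p[i] for i in (1, 2))
    call = (
        tip >= config.tip_fpkm_min
        and fold >= config.tip_fold_min
        and nondecreasing
    )
    return bool(call), {
        "tip": float(tip), "fold": float(fold),
        "nondecreasing": nondecreasing,
    }


# ---------------------------------------------------------------------------
# profile comparison
# ---------------------------------------------------------------------------

def normalize_profile(profile):
    """Max-normalize a profile; returns (unit-scale vector, expressed flag)."""
    p = np.asarray(profile, dtype=float)
    if (p < 0).any():
        raise InvalidSpecError("profiles must be non-negative")
    peak = p.max()
    if peak == 0:
        return p.copy(), False
    return p / peak, True


def _euclidean(p, q):
    return float(np.linalg.norm(p - q) / 2.0)


def profile_divergence(
    p, q, metric: str = "one-minus-pearson", flat_tol: float = 0.2
) -> float:
    """Divergence of two max-normalized profiles; 0 means identical shape.

    one-minus-pearson lies in [0, 2]; euclidean-on-normalized in [0, 1].
    Profiles whose coefficient of variation falls below ``flat_tol`` (flat,
    hence shapeless) are compared by Euclidean distance regardless of the
    requested metric; exactly constant profiles warn.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if metric == "euclidean-on-normalized":
        return _euclidean(p, q)
    if metric != "one-minus-pearson":
        raise InvalidSpecError(f"unknown metric {metric!r}")
    for v in (p, q):
        if np.ptp(v) == 0:
            warnings.warn(
                "constant profile: correlation undefined, using euclidean"
            )
            return _euclidean(p, q)
    if _is_flat(p, flat_tol) or _is_flat(q, flat_tol):
        return _euclidean(p, q)
    r = float(np.corrcoef(p, q)[0, 1])
    return 1.0 - r


def _is_flat(v, flat_tol):
    mu = v.mean()
    return mu == 0 or (v.std() / mu) < flat_tol


# ---------------------------------------------------------------------------
# the three-stage TF filter
# ---------------------------------------------------------------------------

def tf_filter(
    profiles: dict,
    ortholog_map: pd.DataFrame,
    species_info,
    config: ScreenConfig,
    reference: str | None = None,
):
    """Three-stage comparative TF filter.

    ``profiles`` maps species label to a genes x 4 stage-profile DataFrame
    (each species indexed by its own gene ids); ``ortholog_map`` is indexed
    by reference gene id with one column per species (NaN = ortholog absent).

    Stage 1 keeps TFs in the photosynthesis co-expression cluster list;
    stage 2 keeps TFs whose reference-species mean FPKM over the four stages
    is at least ``mean_fpkm_min``; stage 3 compares each C4 species' profile
    with the consensus of the (mutually consistent) C3 profiles and keeps
    TFs diverging in at least one C4 species.  Species without an ortholog
    are recorded as non-comparable, never flagged.

    Returns ``(candidates, attrition)``.
    """
    info = {s.label: s for s in species_info}
    if reference is None:
        reference = species_info[0].label
    if reference not in profiles:
        raise InvalidSpecError(f"reference species {reference!r} has no profiles")
    c3 = [s.label for s in species_info if s.ptype == "C3"]
    c4 = [s.label for s in species_info if s.ptype == "C4"]
    if not c3 or not c4:
        raise InvalidSpecError("need at least one C3 and one C4 species")
    ref_prof = profiles[reference]

    stage1 = [g for g in config.cluster_tf_ids if g in ref_prof.index]
    skipped = [g for g in config.cluster_tf_ids if g not in ref_prof.index]
    if skipped:
        warnings.warn(
            f"{len(skipped)} cluster TF(s) absent from the reference dataset"
        )
    stage2 = [
        g for g in stage1
        if ref_prof.loc[g].mean() >= config.mean_fpkm_min
    ]

    candidates = []
    n_inconsistent = 0
    for gene in stage2:
        orthologs, norm, non_comp = {}, {}, set()
        for sp in (s.label for s in species_info):
            oid = gene if sp == reference else ortholog_map.at[gene, sp] \
                if (gene in ortholog_map.index and sp in ortholog_map.columns) \
                else gene
            if pd.isna(oid) or sp not in profiles or oid not in profiles[sp].index:
                non_comp.add(sp)
                orthologs[sp] = None
                continue
            orthologs[sp] = oid
            vec, expressed = normalize_profile(profiles[sp].loc[oid].to_numpy())
            norm[sp] = vec if expressed else None

        c3_avail = [sp for sp in c3 if sp not in non_comp and norm.get(sp) is not None]
        flags, scores = {}, {}
        if len(c3_avail) >= 2:
            consistent = True
            for i in range(len(c3_avail)):
                for j in range(i + 1, len(c3_avail)):
                    d = profile_divergence(
                        norm[c3_avail[i]], norm[c3_avail[j]],
                        config.divergence_metric, config.flat_tol,
                    )
                    if d > config.c3_consistency_tau:
                        consistent = False
            if not consistent:
                n_inconsistent += 1
                continue
        if c3_avail:
            consensus, _ = normalize_profile(
                np.mean([norm[sp] for sp in c3_avail], axis=0)
            )
            for sp in c4:
                if sp in non_comp:
                    continue
                if norm.get(sp) is None:  # ortholog present but silent
                    scores[sp] = 1.0
                    flags[sp] = True
                    continue
                d = profile_divergence(
                    norm[sp], consensus, config.divergence_metric, config.flat_tol
                )
                scores[sp] = d
                # a divergence flag requires both a shape change beyond
                # divergence_tau and a material normalized difference:
                # correlation alone is heavy-tailed on noisy 4-point profiles
                flags[sp] = (
                    d > config.divergence_tau
                    and _euclidean(norm[sp], consensus) >= config.min_effect
                )
        others_all_missing = all(
            sp in non_comp for sp in info if sp != reference
        )
        if any(flags.values()) or others_all_missing:
            cand = TFCandidate(
                gene=gene, orthologs=orthologs, divergence_flags=flags,
                scores=scores, non_comparable=frozenset(non_comp),
            )
            cand.category = classify_lineage(cand, species_info, reference)
            candidates.append(cand)

    attrition = {
        "cluster": len(config.cluster_tf_ids),
        "in_reference": len(stage1),
        "mean_fpkm": len(stage2),
        "c3_inconsistent": n_inconsistent,
        "candidates": len(candidates),
    }
    return candidates, attrition


def classify_lineage(
    candidate: TFCandidate, species_info, reference: str | None = None
) -> str:
    """Category of a candidate from its per-C4-species divergence flags.

    Divergence in the reference alone is reference-specific; in the
    reference plus every C4 species of the same clade (and no other) it is
    clade-shared (named after the reference clade); in every C4 species it
    is pan-C4; any other pattern is 'none'.  A candidate with no comparable
    species at all defaults to reference-specific.
    """
    info = {s.label: s for s in species_info}
    if reference is None:
        reference = species_info[0].label
    c4 = {s.label for s in species_info if s.ptype == "C4"}
    flagged = {sp for sp, f in candidate.divergence_flags.items() if f}
    if not flagged:
        if candidate.non_comparable >= (set(info) - {reference}):
            return REFERENCE_SPECIFIC
        return NONE
    if reference not in flagged:
        return NONE
    if flagged == {reference}:
        return REFERENCE_SPECIFIC
    if flagged == c4:
        return PAN_C4
    ref_clade = info[reference].clade
    same_clade = {sp for sp in c4 if info[sp].clade == ref_clade}
    if flagged == same_clade:
        return f"{ref_clade}-shared"
    return NONE
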