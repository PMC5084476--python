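"""Diagnostic amino-acid scanning in protein alignments.

C4 lineages repeatedly fix characteristic substitutions in the carbon-shuttle
enzymes — the best known being the alanine-to-serine change at PEPC position
780 (A780S), which relieves malate inhibition.  Sites are specified in the
ungapped coordinates of a chosen reference sequence (1-based, matching
mutation nomenclature such as "A780S") and mapped onto alignment columns, so
classifications are invariant to gap-column placement.

Diagnostic position tables beyond the bundled PEPC example (positively
selected PEPCK sites, NADP-ME, rbcL) are supplied by the user from the
literature; they are data, not code.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import warnings

import numpy as np
import pandas as pd
from Bio import AlignIO

from .errors import GrasskitError, InvalidSpecError

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class DiagnosticSite:
    position: int  # 1-based ungapped reference coordinate
    c3_residue: str
    c4_residues: frozenset

    def __post_init__(self):
        if self.position < 1:
            raise InvalidSpecError("positions are 1-based")
        if self.c3_residue not in VALID_AA or not (
            set(self.c4_residues) <= VALID_AA
        ):
            raise InvalidSpecError("residues must be one-letter amino-acid codes")


@dataclass(frozen=True)
class DiagnosticTable:
    """Diagnostic residue states for one enzyme, in reference numbering."""

    enzyme: str
    reference_id: str
    sites: tuple

    def __post_init__(self):
        pos = [s.position for s in self.sites]
        if pos != sorted(set(pos)):
            raise InvalidSpecError("site positions must be strictly increasing")

    @classmethod
    def from_tsv(cls, path) -> "DiagnosticTable":
        df = pd.read_csv(path, sep="\t")
        enzymes = df["enzyme"].unique()
        refs = df["reference_id"].unique()
        if len(enzymes) != 1 or len(refs) != 1:
            raise InvalidSpecError("one table = one enzyme and one reference")
        sites = tuple(
            DiagnosticSite(
                int(r["position"]), r["c3_residue"], frozenset(r["c4_residues"])
            )
            for _, r in df.sort_values("position").iterrows()
        )
        return cls(str(enzymes[0]), str(refs[0]), sites)


def bundled_pepc_table() -> DiagnosticTable:
    """The bundled example table: PEPC A780S only."""
    with resources.files("grasskit.data").joinpath("pepc_sites.tsv").open() as fh:
        return DiagnosticTable.from_tsv(fh)


def _as_dict(alignment) -> dict[str, str]:
    if isinstance(alignment, dict):
        return {k: str(v).upper() for k, v in alignment.items()}
    return {rec.id: str(rec.seq).upper() for rec in alignment}


def read_alignment(path) -> dict[str, str]:
    return _as_dict(AlignIO.read(path, "fasta"))


def write_alignment(alignment: dict[str, str], path):
    with open(path, "w") as fh:
        for name, seq in alignment.items():
            fh.write(f">{name}\n{seq}\n")


def map_reference_positions(alignment, reference_id: str) -> dict[int, int]:
    """Map 1-based ungapped reference positions to 0-based alignment columns."""
    seqs = _as_dict(alignment)
    if reference_id not in seqs:
        raise GrasskitError(f"reference {reference_id!r} absent from alignment")
    ref = seqs[reference_id]
    mapping = {}
    pos = 0
    for col, ch in enumerate(ref):
        if ch != "-":
            pos += 1
            mapping[pos] = col
    return mapping


@dataclass
class ResidueReport:
    """Per-(sequence, site) residue states plus C4-like summary counts."""

    enzyme: str
    states: pd.DataFrame  # index: sequence id; columns: site positions
    observed: pd.DataFrame

    def c4_counts(self) -> pd.Series:
        return (self.states == "C4-like").sum(axis=1)


def scan(alignment, table: DiagnosticTable) -> ResidueReport:
    """Classify every sequence at every diagnostic site.

    States: 'C4-like' (derived residue), 'C3-like' (ancestral), 'gap', or
    'other'.
    """
    seqs = _as_dict(alignment)
    mapping = map_reference_positions(seqs, table.reference_id)
    ref_len = max(mapping)
    states, observed = {}, {}
    for site in table.sites:
        if site.position > ref_len:
            raise GrasskitError(
                f"site {site.position} beyond reference length {ref_len}"
            )
        col = mapping[site.position]
        st_col, ob_col = {}, {}
        for name, seq in seqs.items():
            aa = seq[col]
            if aa == "-":
                st = "gap"
            elif aa in site.c4_residues:
                st = "C4-like"
            elif aa == site.c3_residue:
                st = "C3-like"
            else:
                st = "other"
            st_col[name], ob_col[name] = st, aa
        states[site.position] = st_col
        observed[site.position] = ob_col
    return ResidueReport(
        table.enzyme, pd.DataFrame(states), pd.DataFrame(observed)
    )


def summarize(report: ResidueReport, min_c4_sites: int = 1) -> pd.DataFrame:
    """Per-sequence C4-like site counts and a signature verdict."""
    counts = report.c4_counts()
    all_gap = (report.states == "gap").all(axis=1)
    if all_gap.any():
        warnings.warn(
            f"all-gap sequence(s) at the diagnostic sites: "
            f"{list(report.states.index[all_gap])}"
        )
    return pd.DataFrame(
        {
            "c4_like_sites": counts,
            "n_sites": len(report.states.columns),
            "verdict": np.where(counts >= min_c4_sites, "C4-signature", "no-signature"),
        }
    )
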