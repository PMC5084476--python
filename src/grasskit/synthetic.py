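"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of its specification (including the seed),
so every downstream result can be checked against a known truth: a circular
quadripartite plastome and the short reads shredded from it, contig sets
with known gap coordinates, a nuclear genome with unique and exactly-twice
duplicated fractions, five-species leaf-gradient expression with planted
C4-divergent regulators, protein alignments with planted diagnostic
residues, and noisy A-Ci observations drawn from either photosynthesis
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import aci as _aci
from ._seq import circular_slice, decode, encode, random_sequence, revcomp
from .c4screen import Species
from .errors import InvalidSpecError
from .gradient import GradientDataset
from .plastome import Contig, PlastomePartition
from .residues import map_reference_positions

# ---------------------------------------------------------------------------
# plastome and reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlastomeSpec:
    """Geometry of a synthetic quadripartite plastome."""

    lsc_len: int = 82_090
    ssc_len: int = 12_572
    ir_len: int = 22_719
    gc_fraction: float = 0.37
    seed: int = 0

    def __post_init__(self):
        if min(self.lsc_len, self.ssc_len, self.ir_len) < 100:
            raise InvalidSpecError(
                "segments too small to embed distinct LSC/SSC/IR regions"
            )
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise InvalidSpecError("gc_fraction must lie in [0, 1]")

    @property
    def total(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len


def generate_plastome(spec: PlastomeSpec) -> tuple[str, PlastomePartition]:
    """Random circular plastome laid out as LSC + IRb + SSC + IRa.

    IRa is exactly the reverse complement of IRb; the returned partition
    records the true boundaries on this canonical linearization.
    """
    rng = np.random.default_rng(spec.seed)
    lsc = random_sequence(spec.lsc_len, spec.gc_fraction, rng)
    irb = random_sequence(spec.ir_len, spec.gc_fraction, rng)
    ssc = random_sequence(spec.ssc_len, spec.gc_fraction, rng)
    # pin the single-copy boundary bases so the inverted repeat is maximal
    # exactly at the designed boundaries (a chance complementary flank would
    # otherwise extend the true repeat by a base or two)
    lsc = "A" + lsc[1:-1] + "A"
    ssc = "A" + ssc[1:-1] + "A"
    seq = lsc + irb + ssc + revcomp(irb)
    part = PlastomePartition(
        lsc_len=spec.lsc_len, irb_len=spec.ir_len,
        ssc_len=spec.ssc_len, ira_len=spec.ir_len,
    )
    return seq, part


@dataclass(frozen=True)
class ReadSimSpec:
    """Shotgun read simulation settings (substitution errors only)."""

    read_len: int = 100
    coverage: float = 50.0
    error_rate: float = 0.0
    paired: bool = False
    insert: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.read_len < 2:
            raise InvalidSpecError("read_len too small")
        if self.coverage < 1:
            raise InvalidSpecError("coverage must be >= 1")
        if not 0.0 <= self.error_rate <= 0.05:
            raise InvalidSpecError("error_rate must lie in [0, 0.05]")


def shred_reads(genome: str, sim: ReadSimSpec) -> list[str]:
    """Shred a circular genome into error-bearing short reads.

    Read count is ceil(coverage * genome length / read_len); start positions
    are uniform on the circle (reads may wrap the origin), strands are
    random, and substitutions are injected i.i.d. at ``error_rate``.
    """
    n = len(genome)
    if n == 0:
        raise InvalidSpecError("empty genome")
    if sim.read_len > n:
        raise InvalidSpecError("read_len exceeds genome length")
    rng = np.random.default_rng(sim.seed)
    n_reads = math.ceil(sim.coverage * n / sim.read_len)
    if sim.paired:
        n_reads += n_reads % 2
    codes = encode(genome.upper())
    doubled = np.concatenate([codes, codes[: sim.read_len]])
    if sim.paired:
        n_frag = n_reads // 2
        frag_starts = rng.integers(0, n, n_frag)
        mate2 = (frag_starts + max(sim.insert, sim.read_len) - sim.read_len) % n
        starts = np.empty(n_reads, dtype=np.int64)
        starts[0::2] = frag_starts
        starts[1::2] = mate2
        reverse = np.zeros(n_reads, dtype=bool)
        reverse[1::2] = True
        flip = rng.random(n_frag) < 0.5
        reverse[0::2] ^= flip
        reverse[1::2] ^= flip
    else:
        starts = rng.integers(0, n, n_reads)
        reverse = rng.random(n_reads) < 0.5
    # doubled array covers reads wrapping the origin
    mat = doubled[starts[:, None] + np.arange(sim.read_len)[None, :]]
    rev_rows = np.nonzero(reverse)[0]
    mat[rev_rows] = 3 - mat[rev_rows, ::-1]
    if sim.error_rate > 0:
        err = rng.random(mat.shape) < sim.error_rate
        shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        mat[err] = (mat[err] + shift) % 4
    flat = decode(mat.reshape(-1))
    L = sim.read_len
    return [flat[i * L : (i + 1) * L] for i in range(n_reads)]


def write_fastq(reads, path, quality: int = 40):
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read_{i}\n{seq}\n+\n{qchar * len(seq)}\n")


def read_fastq(path) -> list[str]:
    from Bio import SeqIO

    return [str(rec.seq) for rec in SeqIO.parse(path, "fastq")]


def seed_contigs(
    genome: str,
    n_gaps: int,
    min_gap: int = 150,
    end_slop: int = 0,
    seed: int = 0,
    min_contig: int = 500,
    max_tries: int = 200,
) -> tuple[list[Contig], dict]:
    """Cut a circular genome into contigs separated by known gaps.

    Gaps are disjoint intervals of length in [min_gap, 2*min_gap); up to
    ``end_slop`` random bases are appended to each contig end to emulate
    misassembled termini (removed downstream by the end-trim rule).  The
    truth record lists gap and contig coordinates on the source circle.
    """
    n = len(genome)
    if n_gaps < 1:
        raise InvalidSpecError("n_gaps must be >= 1")
    rng = np.random.default_rng(seed)
    if n_gaps * (min_gap + min_contig) > n:
        raise InvalidSpecError(
            f"{n_gaps} gaps of >= {min_gap} bp with contigs of >= "
            f"{min_contig} bp cannot fit a {n} bp genome"
        )
    for _ in range(max_tries):
        starts = np.sort(rng.integers(0, n, n_gaps))
        lengths = rng.integers(min_gap, 2 * min_gap, n_gaps)
        ok = True
        for i in range(n_gaps):
            end_i = starts[i] + lengths[i]
            if n_gaps == 1:
                arc = n - lengths[0]
            elif i < n_gaps - 1:
                arc = starts[i + 1] - end_i  # negative when gaps overlap
            else:
                arc = starts[0] + n - end_i
            if arc < min_contig:
                ok = False
                break
        if ok:
            break
    else:
        raise InvalidSpecError(
            f"could not place {n_gaps} disjoint gaps of >= {min_gap} bp "
            f"with contigs of >= {min_contig} bp"
        )
    contigs, contig_iv, gaps = [], [], []
    for i in range(n_gaps):
        g_start, g_len = int(starts[i]), int(lengths[i])
        gaps.append((g_start, (g_start + g_len) % n))
        c_start = (g_start + g_len) % n
        c_end = int(starts[(i + 1) % n_gaps]) if n_gaps > 1 else g_start
        c_len = (c_end - c_start) % n if n_gaps > 1 else n - g_len
        body = circular_slice(genome, c_start, c_len)
        slop5 = random_sequence(int(rng.integers(0, end_slop + 1)), 0.5, rng) \
            if end_slop else ""
        slop3 = random_sequence(int(rng.integers(0, end_slop + 1)), 0.5, rng) \
            if end_slop else ""
        contigs.append(Contig(f"contig_{i}", slop5 + body + slop3))
        contig_iv.append((c_start, c_end if n_gaps > 1 else g_start))
    truth = {"gaps": gaps, "contigs": contig_iv, "genome_length": n}
    return contigs, truth


# ---------------------------------------------------------------------------
# nuclear genome for k-mer sizing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KmerGenomeSpec:
    """Genome with a unique fraction and a block duplicated exactly twice."""

    unique_bp: int = 1_000_000
    duplicated_bp: int = 200_000
    gc_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.unique_bp <= 0 or self.duplicated_bp <= 0:
            raise InvalidSpecError("unique_bp and duplicated_bp must be positive")


def generate_kmer_genome(spec: KmerGenomeSpec) -> tuple[str, dict]:
    """Sequence of length unique_bp + 2*duplicated_bp with a two-copy block."""
    rng = np.random.default_rng(spec.seed)
    unique = random_sequence(spec.unique_bp, spec.gc_fraction, rng)
    dup = random_sequence(spec.duplicated_bp, spec.gc_fraction, rng)
    half = spec.unique_bp // 2
    seq = unique[:half] + dup + unique[half:] + dup
    truth = {
        "unique_bp": spec.unique_bp,
        "duplicated_bp": spec.duplicated_bp,
        "total_bp": spec.unique_bp + 2 * spec.duplicated_bp,
        "dup_intervals": [
            (half, half + spec.duplicated_bp),
            (spec.unique_bp + spec.duplicated_bp,
             spec.unique_bp + 2 * spec.duplicated_bp),
        ],
    }
    return seq, truth


# ---------------------------------------------------------------------------
# leaf gradients with planted divergent regulators
# ---------------------------------------------------------------------------

def default_species() -> list[Species]:
    """The five-species comparison: reference C4 Andropogoneae first."""
    return [
        Species("Zm", "C4", "Andropogoneae"),
        Species("Sb", "C4", "Andropogoneae"),
        Species("Sv", "C4", "Paniceae"),
        Species("Do", "C3", "Paniceae"),
        Species("Os", "C3", "BEP"),
    ]


@dataclass(frozen=True)
class PlantedTF:
    """A regulator whose profile is perturbed in the named C4 species."""

    tf_index: int
    pattern: frozenset  # C4 species labels carrying the divergence
    fold: float = 4.0
    segments: tuple = (3, 4)  # 1-based stages receiving the fold


@dataclass(frozen=True)
class GradientDesign:
    """Design of the multi-species synthetic leaf-gradient experiment."""

    species: tuple = field(default_factory=lambda: tuple(default_species()))
    n_genes: int = 1000
    n_tf: int = 200
    n_segments: int = 4
    n_replicates: int = 3
    planted: tuple = ()
    noise_cv: float = 0.2
    ortholog_dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 2:
            raise InvalidSpecError("need at least 2 replicates per segment")
        if self.n_segments != 4:
            raise InvalidSpecError("the gradient design uses 4 segments")
        if self.n_tf > self.n_genes:
            raise InvalidSpecError("n_tf cannot exceed n_genes")
        c4 = {s.label for s in self.species if s.ptype == "C4"}
        for p in self.planted:
            if not 0 <= p.tf_index < self.n_tf:
                raise InvalidSpecError(f"planted tf_index {p.tf_index} out of range")
            if not p.pattern or not set(p.pattern) <= c4:
                raise InvalidSpecError(
                    "divergence patterns must be non-empty subsets of the "
                    "C4 species"
                )


#: smooth 4-point base shapes (mean 1), the photosynthesis-like repertoire
SHAPE_LIBRARY = {
    "flat": np.array([1.0, 1.0, 1.0, 1.0]),
    "increasing": np.array([0.25, 0.75, 1.25, 1.75]),
    "decreasing": np.array([1.75, 1.25, 0.75, 0.25]),
    "peaked": np.array([0.5, 1.5, 1.5, 0.5]),
}


@dataclass
class SyntheticGradient:
    """Generated datasets plus the planted truth and the ortholog map."""

    datasets: dict
    planted: pd.DataFrame
    ortholog_map: pd.DataFrame
    tf_ids: list
    design: GradientDesign


def generate_gradient(design: GradientDesign) -> SyntheticGradient:
    """Simulate the five-species leaf-gradient FPKM tensors.

    Background genes share one per-gene base profile across species (a
    log-normal expression level times a smooth 4-point shape); replicate
    noise is multiplicative log-normal with CV ``noise_cv``.  Planted
    regulators carry their fold perturbation on the designated segments only
    in the species named by their divergence pattern; they are assigned the
    'decreasing' base shape (high in immature tissue) so a tip-ward
    induction genuinely changes the profile shape.
    """
    rng = np.random.default_rng(design.seed)
    shapes = list(SHAPE_LIBRARY)
    genes = [f"TF{i:04d}" for i in range(design.n_tf)] + [
        f"G{i:05d}" for i in range(design.n_genes - design.n_tf)
    ]
    planted_by_idx = {p.tf_index: p for p in design.planted}

    shape_idx = rng.integers(0, len(shapes), design.n_genes)
    # amplitude <= 1 keeps every shape strictly positive (library min 0.25)
    amp = rng.uniform(0.4, 1.0, design.n_genes)
    levels = rng.lognormal(mean=np.log(8.0), sigma=1.2, size=design.n_genes)
    base = np.empty((design.n_genes, 4))
    for g in range(design.n_genes):
        if g in planted_by_idx:
            # planted regulators: expressed, with the full-amplitude
            # decreasing base shape (high in immature tissue) so the C4
            # perturbation genuinely reshapes the profile
            shape = SHAPE_LIBRARY["decreasing"]
            levels[g] = rng.lognormal(mean=np.log(50.0), sigma=0.3)
            base[g] = levels[g] * shape
        else:
            shape = SHAPE_LIBRARY[shapes[shape_idx[g]]]
            base[g] = levels[g] * (1.0 + amp[g] * (shape - 1.0))
    base = np.clip(base, 0.05, None)

    sigma = math.sqrt(math.log(1.0 + design.noise_cv**2))
    datasets = {}
    for sp in design.species:
        prof = base.copy()
        for g, p in planted_by_idx.items():
            if sp.label in p.pattern:
                for seg in p.segments:
                    prof[g, seg - 1] *= p.fold
        reps = design.n_replicates
        noise = np.exp(
            rng.normal(0.0, sigma, size=(design.n_genes, 4, reps))
            - sigma**2 / 2.0
        ) if design.noise_cv > 0 else np.ones((design.n_genes, 4, reps))
        tensor = prof[:, :, None] * noise
        cols = pd.MultiIndex.from_product(
            [range(1, 5), range(1, reps + 1)], names=["segment", "replicate"]
        )
        df = pd.DataFrame(
            tensor.reshape(design.n_genes, 4 * reps), index=genes, columns=cols
        )
        datasets[sp.label] = GradientDataset(sp.label, df)

    reference = design.species[0].label
    omap = pd.DataFrame(
        {s.label: genes for s in design.species}, index=genes
    )
    if design.ortholog_dropout > 0:
        tf_rows = np.arange(design.n_tf)
        drop = tf_rows[rng.random(design.n_tf) < design.ortholog_dropout]
        for g in drop:
            for s in design.species:
                if s.label != reference:
                    omap.iloc[g, omap.columns.get_loc(s.label)] = np.nan
    planted_df = pd.DataFrame(
        [
            {
                "gene": genes[p.tf_index],
                "pattern": "+".join(sorted(p.pattern)),
                "fold": p.fold,
                "segments": "+".join(str(s) for s in p.segments),
            }
            for p in design.planted
        ],
        columns=["gene", "pattern", "fold", "segments"],
    )
    return SyntheticGradient(
        datasets=datasets,
        planted=planted_df,
        ortholog_map=omap,
        tf_ids=genes[: design.n_tf],
        design=design,
    )


# ---------------------------------------------------------------------------
# protein alignments with planted residues
# ---------------------------------------------------------------------------

def synthetic_protein_alignment(
    n_seqs: int = 6,
    length: int = 970,
    reference_id: str = "REF",
    divergence: float = 0.1,
    gap_columns: int = 0,
    seed: int = 0,
) -> dict[str, str]:
    """A synthetic aligned protein family around an ungapped reference.

    Non-reference sequences differ from the reference at ~``divergence`` of
    positions; ``gap_columns`` alignment columns carry gaps in a random
    subset of non-reference sequences.
    """
    rng = np.random.default_rng(seed)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    ref = aas[rng.integers(0, 20, length)]
    aln = {reference_id: "".join(ref)}
    for i in range(n_seqs - 1):
        seq = ref.copy()
        mut = rng.random(length) < divergence
        seq[mut] = aas[rng.integers(0, 20, int(mut.sum()))]
        if gap_columns:
            cols = rng.choice(length, size=min(gap_columns, length), replace=False)
            keep = rng.random(len(cols)) < 0.5
            seq[cols[keep]] = "-"
        aln[f"seq{i + 1}"] = "".join(seq)
    return aln


def generate_alignment(
    template: dict[str, str],
    plants,
    reference_id: str = "REF",
) -> dict[str, str]:
    """Plant residues at reference-numbered positions in an alignment.

    ``plants`` is an iterable of ``(sequence_id, reference_position,
    residue)`` with positions 1-based in the reference's ungapped sequence.
    All other columns are untouched.
    """
    aln = {k: str(v) for k, v in template.items()}
    mapping = map_reference_positions(aln, reference_id)
    for seq_id, pos, residue in plants:
        if pos not in mapping:
            raise InvalidSpecError(
                f"position {pos} beyond reference length {max(mapping)}"
            )
        if seq_id not in aln:
            raise InvalidSpecError(f"sequence {seq_id!r} absent from template")
        col = mapping[pos]
        s = aln[seq_id]
        aln[seq_id] = s[:col] + residue + s[col + 1 :]
    return aln


# ---------------------------------------------------------------------------
# A-Ci observations
# ---------------------------------------------------------------------------

def default_ci_grid() -> np.ndarray:
    """The measurement pressures converted to ubar (1 Pa = 10 ubar)."""
    return np.array(sorted(_aci.MEASUREMENT_PA)) * _aci.UBAR_PER_PA


def simulate_aci(
    params: _aci.AciModelParams,
    ci_grid=None,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy gas-exchange observations from a model curve."""
    ci = np.asarray(
        default_ci_grid() if ci_grid is None else ci_grid, dtype=float
    )
    if (ci <= 0).any():
        raise InvalidSpecError("ci grid must be positive")
    curve = _aci.model_curve(ci, params)
    rng = np.random.default_rng(seed)
    a = curve.a + (rng.normal(0.0, noise_sd, len(ci)) if noise_sd > 0 else 0.0)
    return pd.DataFrame({"ci_ubar": ci, "a_umol": a})
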