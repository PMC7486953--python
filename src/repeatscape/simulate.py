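"""Synthetic repeatome generator with planted truth.

Generates per-species genomes containing repeat families of the major classes
(satellite, helitron, LINE, LTR, SINE, DNA transposon) at controlled copy
numbers, evolves family copies along a fixed species tree under Jukes-Cantor
substitution, and samples uniform low-coverage reads with sequencing error.
Every genome records truth intervals (which positions belong to which family)
and every read carries its truth provenance, so downstream estimates can be
scored against a known answer.

Copy-number dynamics: a family originates at a node of the species tree with
a given number of identical ancestral copies; along each branch the copy
count is multiplied by a per-branch fold change (duplicating or dropping
copies at the start of the branch) and every copy then accumulates
substitutions at ``divergence_rate x branch length``. Copies expanded after a
species split therefore carry species-private mutations, while copies that
diverged before the split are shared - the contrast the pool-and-paint
analysis is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import decode, derive_seed, encode
from .asr import Phylogeny
from .cluster import Read

REPEAT_CLASSES = ("satellite", "helitron", "LINE", "LTR", "SINE", "DNA_transposon")

#: Standard C-value conversion: 1 pg of DNA corresponds to 978 Mb.
MB_PER_PG = 978.0
BASES_PER_PG = MB_PER_PG * 1e6


@dataclass
class RepeatFamilySpec:
    """Parameters of one planted repeat family.

    ``branch_multipliers`` maps branch ids (child-node ids of the species
    tree) to fold changes in copy number along that branch; branches absent
    from the map keep the copy count unchanged. ``divergence_rate`` is in
    substitutions per site per unit branch length (Jukes-Cantor).
    ``origin_node`` names the tree node where the family first exists (None =
    root); only species descending from it receive copies.
    """

    family_id: str
    repeat_class: str
    unit_length: int
    ancestral_copies: int
    branch_multipliers: dict[str, float] = field(default_factory=dict)
    divergence_rate: float = 0.05
    origin_node: str | None = None

    def __post_init__(self):
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {self.repeat_class!r}")
        if self.unit_length < 20:
            raise ValueError("unit_length must be >= 20")
        if self.ancestral_copies < 0:
            raise ValueError("ancestral_copies must be >= 0")
        if any(m < 0 for m in self.branch_multipliers.values()):
            raise ValueError("branch multipliers must be >= 0")


@dataclass
class SpeciesGenome:
    species_id: str
    sequence: str
    truth_intervals: list[tuple[int, int, str]]  # (start, end, family_id|"background")
    genome_size_pg: float

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def repeat_fraction(self) -> float:
        """Recomputed from truth intervals: repeat bases / total bases."""
        rep = sum(e - s for s, e, lab in self.truth_intervals if lab != "background")
        return rep / self.length


@dataclass
class SimulatedReadSet:
    reads: list[Read]
    coverage: float
    read_length: int
    error_rate: float
    seed: int


class ConfigurationError(ValueError):
    pass


def _jc_mutate(copies: np.ndarray, rate: float, branch_length: float,
               rng: np.random.Generator) -> np.ndarray:
    """Exact Jukes-Cantor transition applied in place to coded copies.

    P(site differs after time v) = 3/4 (1 - exp(-4 r v / 3)); a changed site
    takes one of the other three bases uniformly.
    """
    p_change = 0.75 * (1.0 - np.exp(-4.0 * rate * branch_length / 3.0))
    if p_change <= 0:
        return copies
    mask = rng.random(copies.shape) < p_change
    shifts = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
    copies[mask] = (copies[mask] + shifts) % 4
    return copies


def evolve_family(tree: Phylogeny, spec: RepeatFamilySpec,
                  seed: int) -> dict[str, list[str]]:
    """Evolve one family's copies along the species tree.

    Returns a map from species id to the list of copy sequences present in
    that species (empty outside the clade descending from ``origin_node``).
    """
    node_ids = set(tree.postorder())
    unknown = [b for b in spec.branch_multipliers if b not in node_ids or b == tree.root]
    if unknown:
        raise ConfigurationError(
            f"family {spec.family_id!r}: unknown branch id(s) {unknown}")
    origin = spec.origin_node if spec.origin_node is not None else tree.root
    if origin not in node_ids:
        raise ConfigurationError(
            f"family {spec.family_id!r}: unknown origin node {origin!r}")

    rng = np.random.default_rng(derive_seed(seed, f"family:{spec.family_id}"))
    unit = rng.integers(0, 4, size=spec.unit_length, dtype=np.uint8)
    copies_at = {origin: np.tile(unit, (spec.ancestral_copies, 1))}

    out: dict[str, list[str]] = {t: [] for t in tree.tips}
    stack = [origin]
    while stack:
        node = stack.pop()
        copies = copies_at.pop(node)
        if tree.is_tip(node):
            out[node] = [decode(c) for c in copies]
            continue
        for child in tree.children(node):
            # copy-number change is applied at the branch midpoint: new
            # copies share the first half of the branch with their template
            # and accumulate private mutations over the second half
            half = tree.branch_length(child) / 2.0
            mult = spec.branch_multipliers.get(child, 1.0)
            branch_copies = copies.copy()
            _jc_mutate(branch_copies, spec.divergence_rate, half, rng)
            n_new = int(round(branch_copies.shape[0] * mult))
            if n_new > branch_copies.shape[0] and branch_copies.shape[0] > 0:
                extra = rng.integers(0, branch_copies.shape[0],
                                     size=n_new - branch_copies.shape[0])
                branch_copies = np.vstack([branch_copies, branch_copies[extra]])
            elif n_new < branch_copies.shape[0]:
                if n_new > 0:
                    keep = rng.choice(branch_copies.shape[0], size=n_new,
                                      replace=False)
                    branch_copies = branch_copies[np.sort(keep)]
                else:
                    branch_copies = branch_copies[:0].copy()
            _jc_mutate(branch_copies, spec.divergence_rate, half, rng)
            copies_at[child] = branch_copies
            stack.append(child)
    return out


def build_genome(species_id: str,
                 families: list[tuple[RepeatFamilySpec, list[str]]],
                 background_length: int, seed: int,
                 min_gap: int = 0) -> SpeciesGenome:
    """Assemble a genome from repeat copies and random single-copy background.

    Satellite copies are concatenated into one tandem array; copies of all
    other classes are dispersed at random positions. Truth intervals tile the
    genome without gaps or overlap. ``min_gap`` forces at least that much
    background between consecutive repeat blocks (a gap of one read length
    makes families unbridgeable by read chains, i.e. "well separated");
    the default 0 allows repeats to abut, as real repeats do.
    """
    if background_length <= 0:
        raise ValueError("background_length must be positive")
    rng = np.random.default_rng(derive_seed(seed, f"genome:{species_id}"))

    # a block is a run of intervals kept adjacent in the final genome
    blocks: list[list[tuple[str, str]]] = []
    for spec, copies in families:
        if not copies:
            continue
        if spec.repeat_class == "satellite":
            blocks.append([(c, spec.family_id) for c in copies])
        else:
            blocks.extend([[(c, spec.family_id)] for c in copies])
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    background = rng.integers(0, 4, size=background_length, dtype=np.uint8)
    n_slots = len(blocks) + 1
    if min_gap > 0:
        spare = background_length - n_slots * min_gap
        if spare < 0:
            raise ValueError(
                f"background_length {background_length} too small for "
                f"{len(blocks)} blocks with min_gap {min_gap}")
        cuts = np.sort(rng.integers(0, spare + 1, size=len(blocks)))
        sizes = np.diff(np.concatenate([[0], cuts, [spare]])) + min_gap
        bg_segments = np.split(background, np.cumsum(sizes)[:-1])
    else:
        cuts = np.sort(rng.integers(0, background_length + 1, size=len(blocks)))
        bg_segments = np.split(background, cuts)

    parts: list[str] = []
    intervals: list[tuple[int, int, str]] = []
    pos = 0

    def _push(seq: str, label: str):
        nonlocal pos
        if seq:
            parts.append(seq)
            intervals.append((pos, pos + len(seq), label))
            pos += len(seq)

    for i, block in enumerate(blocks):
        _push(decode(bg_segments[i]), "background")
        for copy_seq, fam in block:
            _push(copy_seq, fam)
    _push(decode(bg_segments[-1]) if len(bg_segments) > len(blocks) else "",
          "background")

    sequence = "".join(parts)
    if not sequence:
        raise ValueError("genome has zero length")
    return SpeciesGenome(
        species_id=species_id,
        sequence=sequence,
        truth_intervals=intervals,
        genome_size_pg=len(sequence) / BASES_PER_PG,
    )


def sample_reads(genome: SpeciesGenome, coverage: float, read_length: int,
                 error_rate: float, seed: int, platform: str = "short",
                 sample_id: str | None = None) -> SimulatedReadSet:
    """Sample uniform single-end reads from both strands with substitution error.

    The read count is ``round(coverage x genome length / read_length)``.
    Truth provenance is taken from the interval containing the read midpoint.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if read_length > genome.length:
        raise ValueError("read_length exceeds genome length")
    sample_id = sample_id or genome.species_id
    rng = np.random.default_rng(
        derive_seed(seed, f"reads:{sample_id}:{platform}"))
    length = genome.length
    n_reads = int(round(coverage * length / read_length))
    genome_codes = encode(genome.sequence)
    starts = rng.integers(0, length - read_length + 1, size=n_reads)
    flip = rng.random(n_reads) < 0.5

    bounds = np.array([s for s, _, _ in genome.truth_intervals])
    labels = [lab for _, _, lab in genome.truth_intervals]

    reads: list[Read] = []
    for i in range(n_reads):
        s = int(starts[i])
        codes = genome_codes[s:s + read_length].copy()
        if error_rate > 0:
            err = rng.random(read_length) < error_rate
            shifts = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
            codes[err] = (codes[err] + shifts) % 4
        if flip[i]:
            codes = 3 - codes[::-1]  # reverse complement in code space
        mid = s + read_length // 2
        prov = labels[int(np.searchsorted(bounds, mid, side="right")) - 1]
        reads.append(Read(
            read_id=f"{sample_id}|{platform}|{i}",
            sample_id=sample_id,
            platform=platform,
            sequence=decode(codes),
            provenance=prov,
        ))
    return SimulatedReadSet(reads=reads, coverage=coverage,
                            read_length=read_length, error_rate=error_rate,
                            seed=seed)
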