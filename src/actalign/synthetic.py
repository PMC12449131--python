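"""Seeded synthetic sequence datasets and mutated pairs.

Every stage of the package is testable without downloads: this module
draws random sequence sets whose counts and length ranges emulate, at
reduced scale, the shapes of typical gene-family benchmark sets (tens to
hundreds of sequences, hundreds to thousands of bases), and derives
mutated copies of a sequence with known per-site edit rates so tests can
bound alignment scores from the recorded ground-truth edits.

Randomness is a single seeded stream split per sequence by counter, so
growing ``n_sequences`` never changes earlier records and identical specs
reproduce identical FASTA bytes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Tuple

import numpy as np

from actalign.core import ConfigurationError, DNA_ALPHABET, ScoringScheme, Sequence


@dataclass(frozen=True)
class DatasetSpec:
    """Shape of a synthetic dataset: ``n_sequences`` sequences with lengths
    uniform on [min_len, max_len] over ``alphabet`` (ambiguity codes are
    never generated)."""

    n_sequences: int
    min_len: int
    max_len: int
    alphabet: str = "ACGT"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ConfigurationError("n_sequences must be >= 1")
        if not (0 <= self.min_len <= self.max_len):
            raise ConfigurationError("need 0 <= min_len <= max_len")
        if not self.alphabet:
            raise ConfigurationError("alphabet must be non-empty")


@dataclass(frozen=True)
class MutationSpec:
    """Independent per-site edit rates; their sum must stay below 1 so a
    site can remain unedited."""

    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (self.substitution_rate, self.insertion_rate, self.deletion_rate)
        if any(r < 0 or r >= 1 for r in rates):
            raise ConfigurationError("each rate must lie in [0, 1)")
        if sum(rates) >= 1:
            raise ConfigurationError("rates must sum to < 1")


class Edit(NamedTuple):
    position: int  # 0-based position in the original sequence
    kind: str  # substitution | insertion | deletion
    residue: str  # new residue ('' for deletion)


class MutatedPair(NamedTuple):
    original: Sequence
    mutated: Sequence
    edits: Tuple[Edit, ...]
    #: gapped truth strings of the generating edit script (original on top)
    truth_query: str
    truth_target: str


def random_sequences(spec: DatasetSpec) -> List[Sequence]:
    """Draw ``n_sequences`` deterministic sequences for the spec's seed."""
    letters = np.frombuffer(spec.alphabet.encode(), dtype=np.uint8)
    out: List[Sequence] = []
    for k in range(spec.n_sequences):
        rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, k])
        length = int(rng.integers(spec.min_len, spec.max_len + 1))
        codes = rng.integers(0, len(letters), size=length)
        residues = letters[codes].tobytes().decode()
        out.append(Sequence(f"seq{k:04d}", residues, alphabet=_alphabet_for(spec.alphabet)))
    return out


def _alphabet_for(generating: str) -> str:
    """Sequences drawn over ACGT (or a subset) still declare the standard
    DNA alphabet so they mix with FASTA inputs; other alphabets pass
    through unchanged."""
    return DNA_ALPHABET if set(generating) <= set(DNA_ALPHABET) else generating


def mutate_pair(seq: Sequence, spec: MutationSpec) -> MutatedPair:
    """Return the original and a mutated copy with known edits.

    Per original site, at most one edit applies (deletion, substitution to
    a different residue, or insertion of one residue after the site); the
    edit list and the gapped truth alignment of the generating script are
    returned for test introspection.  The optimal local alignment score of
    the pair is always >= the re-scored truth path.
    """
    rng = np.random.default_rng(spec.seed & 0x7FFFFFFF)
    bases = list("ACGT")
    mutated: List[str] = []
    edits: List[Edit] = []
    tq: List[str] = []
    tt: List[str] = []
    for pos, a in enumerate(seq.residues):
        u = rng.random()
        if u < spec.deletion_rate:
            edits.append(Edit(pos, "deletion", ""))
            tq.append(a)
            tt.append("-")
            continue
        u -= spec.deletion_rate
        if u < spec.substitution_rate:
            b = str(rng.choice([c for c in bases if c != a] or bases))
            mutated.append(b)
            edits.append(Edit(pos, "substitution", b))
            tq.append(a)
            tt.append(b)
        else:
            mutated.append(a)
            tq.append(a)
            tt.append(a)
        u2 = rng.random()
        if u2 < spec.insertion_rate:
            b = str(rng.choice(bases))
            mutated.append(b)
            edits.append(Edit(pos, "insertion", b))
            tq.append("-")
            tt.append(b)
    out = Sequence(seq.id + "_mut", "".join(mutated), alphabet=seq.alphabet)
    return MutatedPair(seq, out, tuple(edits), "".join(tq), "".join(tt))


def brca1_like_spec(seed: int = 0) -> DatasetSpec:
    """A reduced-scale gene-family shape: 30 sequences of 500-1050 bases
    (a desk-scale stand-in for collections of a few hundred multi-kilobase
    gene sequences)."""
    return DatasetSpec(n_sequences=30, min_len=500, max_len=1050, seed=seed)


FIXTURE_PROFILES = {
    # reduced-scale emulations of typical benchmark shapes:
    # (n_sequences, min_len, max_len)
    "gene_small": (20, 300, 700),
    "gene_medium": (30, 500, 1050),
    "mixed_lengths": (40, 50, 400),
    "short_reads": (60, 80, 120),
}


def make_fixtures(out_dir, seed: int = 0) -> List[str]:
    """Write the reduced-scale FASTA fixture suite; returns written paths."""
    from pathlib import Path

    from actalign.io import write_fasta

    out = []
    for name, (n, lo, hi) in FIXTURE_PROFILES.items():
        spec = DatasetSpec(n_sequences=n, min_len=lo, max_len=hi, seed=seed)
        path = Path(out_dir) / f"{name}.fasta"
        write_fasta(random_sequences(spec), path)
        out.append(str(path))
    return out
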