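"""The standard genetic code as a single-substitution mutation graph.

Every downstream statistic in this package (motif gain/loss path ratios,
near-site classification, neutral-simulation event classification) is a
count over the 64 x 9 directed single-nucleotide-substitution events between
codons.  This module owns that graph: codon neighborhoods, codon blocks
treated as synonymous units, stop-codon policy, and optional per-codon
usage weights.

Conventions
-----------
* DNA alphabet (``ACGT``), uppercase; codons are 3-letter strings.
* The substitution relation is symmetric: nine raw neighbors per codon.
* Stop policy ``"exclude"`` (the default) removes events into the three
  stop codons from every motif-relevant count; ``"include"`` keeps them,
  which is needed for the exhaustive 4^6 two-codon enumeration where a
  neighbor's identity may be a stop codon.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, Mapping, Optional, Tuple

NUCLEOTIDES = "ACGT"

#: NCBI translation table 1 (the standard code), DNA alphabet, '*' = stop.
STANDARD_CODE: Dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS: FrozenSet[str] = frozenset(
    c for c, a in STANDARD_CODE.items() if a == "*"
)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class InputError(ValueError):
    """Raised on contract violations in user-supplied inputs."""


def _validate_codon(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(ch not in NUCLEOTIDES for ch in codon):
        raise InputError(f"not a valid codon over ACGT: {codon!r}")
    return codon


def codon_neighbors(codon: str) -> FrozenSet[str]:
    """The 9 codons differing from ``codon`` at exactly one position.

    Stop codons are legal both as input and among the neighbors; filtering
    is the caller's (or the graph's) job.
    """
    codon = _validate_codon(codon)
    out = set()
    for i in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[i]:
                out.add(codon[:i] + nt + codon[i + 1:])
    return frozenset(out)


@dataclass(frozen=True)
class CodonTable:
    """The 64-codon table with the 61/3 sense/stop partition."""

    codon_to_aa: Mapping[str, str]
    stops: FrozenSet[str]

    @classmethod
    def standard(cls) -> "CodonTable":
        return cls(codon_to_aa=dict(STANDARD_CODE), stops=STOP_CODONS)

    def __post_init__(self) -> None:
        sense = [c for c in self.codon_to_aa if c not in self.stops]
        if len(self.codon_to_aa) != 64 or len(self.stops) != 3:
            raise InputError("codon table must have 64 codons and 3 stops")
        if len(sense) != 61:
            raise InputError("codon table must have 61 sense codons")

    @property
    def sense_count(self) -> int:
        return 61

    @property
    def sense_codons(self) -> Tuple[str, ...]:
        return tuple(sorted(c for c in self.codon_to_aa if c not in self.stops))

    def translate(self, cds: str) -> str:
        cds = cds.upper()
        if len(cds) % 3:
            raise InputError("CDS length not divisible by 3")
        return "".join(
            self.codon_to_aa[_validate_codon(cds[i:i + 3])]
            for i in range(0, len(cds), 3)
        )

    def codons_for(self, amino_acids: Iterable[str]) -> FrozenSet[str]:
        wanted = set(amino_acids)
        return frozenset(
            c for c, a in self.codon_to_aa.items()
            if a in wanted and c not in self.stops
        )


@dataclass(frozen=True)
class CodonBlock:
    """A named set of sense codons treated as mutually synonymous.

    The motif calculus treats e.g. the 10 Ser/Thr codons as one identity:
    a substitution between two block members is synonymous for motif
    purposes even when it changes the amino acid.
    """

    name: str
    codons: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.codons:
            raise InputError(f"empty codon block {self.name!r}")
        object.__setattr__(
            self, "codons", frozenset(_validate_codon(c) for c in self.codons)
        )
        bad = self.codons & STOP_CODONS
        if bad:
            raise InputError(f"block {self.name!r} contains stop codons {sorted(bad)}")

    @classmethod
    def for_amino_acids(
        cls, amino_acids: str, table: Optional[CodonTable] = None,
        name: Optional[str] = None,
    ) -> "CodonBlock":
        table = table or CodonTable.standard()
        return cls(name=name or amino_acids, codons=table.codons_for(amino_acids))

    def __len__(self) -> int:
        return len(self.codons)

    def __contains__(self, codon: str) -> bool:
        return codon in self.codons


#: The two blocks of the N-glycosylation sequon.
ASN_BLOCK = CodonBlock("Asn", frozenset({"AAT", "AAC"}))
SER_THR_BLOCK = CodonBlock(
    "Ser/Thr",
    frozenset({"TCT", "TCC", "TCA", "TCG", "AGT", "AGC",
               "ACT", "ACC", "ACA", "ACG"}),
)
PRO_CODONS = frozenset({"CCT", "CCC", "CCA", "CCG"})


@dataclass
class MutationGraph:
    """Single-substitution adjacency over the 64 codons.

    Parameters
    ----------
    stop_policy : {"exclude", "include"}
        Whether events whose destination is a stop codon are counted.
    weights : mapping codon -> float, optional
        Per-codon usage weights over sense codons; normalized to sum to 1.
        When absent, every codon carries equal weight (the reproducible
        default; a usage table from a real transcriptome may be supplied
        per analysis).
    """

    table: CodonTable = field(default_factory=CodonTable.standard)
    stop_policy: str = "exclude"
    weights: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.stop_policy not in ("exclude", "include"):
            raise InputError(f"unknown stop policy {self.stop_policy!r}")
        if self.weights is not None:
            w = {_validate_codon(c): float(v) for c, v in self.weights.items()
                 if c not in self.table.stops}
            total = sum(w.values())
            if total <= 0:
                raise InputError("usage weights must have positive total")
            self.weights = {c: v / total for c, v in w.items()}

    # -- plumbing -----------------------------------------------------------

    def weight(self, codon: str) -> float:
        if self.weights is None:
            return 1.0
        return self.weights.get(codon, 0.0)

    def _counted(self, dest: str) -> bool:
        return self.stop_policy == "include" or dest not in self.table.stops

    def iter_events(self, sources: Iterable[str]) -> Iterator[Tuple[str, str]]:
        """Directed substitution events out of ``sources``, stop policy applied."""
        for c in sources:
            for n in codon_neighbors(c):
                if self._counted(n):
                    yield c, n

    # -- block-level counts -------------------------------------------------

    def neighbor_set(self, block: CodonBlock,
                     exclude_stops: Optional[bool] = None) -> FrozenSet[str]:
        """Distinct codons one substitution from any block member.

        Block members themselves are excluded; stops are removed iff
        ``exclude_stops`` (defaulting to the graph's stop policy).
        """
        if exclude_stops is None:
            exclude_stops = self.stop_policy == "exclude"
        out = set()
        for c in block.codons:
            out |= codon_neighbors(c)
        out -= block.codons
        if exclude_stops:
            out -= self.table.stops
        return frozenset(out)

    def exit_counts(self, block: CodonBlock) -> Dict[str, Dict[str, int]]:
        """Per-codon tally of {synonymous, stop, destroying} exit events."""
        out = {}
        for c in block.codons:
            syn = stop = dest = 0
            for n in codon_neighbors(c):
                if n in block.codons:
                    syn += 1
                elif n in self.table.stops:
                    stop += 1
                else:
                    dest += 1
            out[c] = {"synonymous": syn, "stop": stop, "destroying": dest}
        return out

    def mean_destroying(self, block: CodonBlock) -> float:
        """Usage-weighted mean count of block-destroying exits per codon.

        A destroying exit leaves the block without landing on a stop
        (stop-destined events are never counted as destroying; with
        ``stop_policy="include"`` they are still excluded here because a
        path through a stop codon cannot occur in a coding sequence).
        """
        counts = self.exit_counts(block)
        num = sum(self.weight(c) * counts[c]["destroying"] for c in block.codons)
        den = sum(self.weight(c) for c in block.codons)
        if den == 0:
            raise InputError(f"block {block.name!r} has zero total usage weight")
        return num / den

    def nonsyn_fraction(self, block: CodonBlock) -> float:
        """Fraction of single-substitution events from the block that leave it.

        Denominator is all 9 events per source codon; with the default
        ``exclude`` stop policy, events into stop codons are removed from
        the numerator only (they neither retain nor destroy the block in a
        viable sequence).  Events are usage-weighted by source codon.
        """
        counts = self.exit_counts(block)
        num = den = 0.0
        for c in block.codons:
            w = self.weight(c)
            dest = counts[c]["destroying"]
            if self.stop_policy == "include":
                dest += counts[c]["stop"]
            num += w * dest
            den += w * 9
        if den == 0:
            raise InputError(f"block {block.name!r} has zero total usage weight")
        return num / den

    def paths_between(self, source_block: CodonBlock,
                      dest_block: CodonBlock) -> int:
        """Directed single-substitution events from one block into another."""
        if source_block.codons & dest_block.codons:
            raise InputError("paths_between requires disjoint blocks")
        return sum(
            1 for _, dst in self.iter_events(sorted(source_block.codons))
            if dst in dest_block.codons
        )

    def in_path_counts(self, dest_block: CodonBlock) -> Dict[str, int]:
        """For each near codon, the number of substitution paths into the block.

        Near codons are the graph-policy neighbor set; stop codons are never
        sources when the policy excludes them.
        """
        near = self.neighbor_set(dest_block)
        return {
            c: sum(1 for n in codon_neighbors(c) if n in dest_block.codons)
            for c in sorted(near)
        }

    def mean_in_paths(self, dest_block: CodonBlock) -> float:
        """Usage-weighted mean in-paths per member of the neighbor set."""
        counts = self.in_path_counts(dest_block)
        num = sum(self.weight(c) * k for c, k in counts.items())
        den = sum(self.weight(c) for c in counts)
        if den == 0:
            raise InputError("neighbor set has zero total usage weight")
        return num / den

    def multi_path_codons(self, dest_block: CodonBlock, k: int) -> FrozenSet[str]:
        """Codons with at least ``k`` substitution paths into the block."""
        if k < 1:
            raise InputError("k must be >= 1")
        return frozenset(
            c for c, n in self.in_path_counts(dest_block).items() if n >= k
        )
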