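"""Serial random mutagenesis of coding sequences with sequon event logging.

The simulator applies single-nucleotide substitutions to a CDS one at a
time: a uniformly chosen position is changed to a uniformly chosen
alternative nucleotide; proposals that would create an in-frame stop codon
are rejected and resampled (zero tolerance for stops, no indels).  An
optional acceptance probability for amino-acid replacements models
purifying selection; at 1.0 the process is strictly neutral.

Branch length is the expected number of *accepted* substitutions per
nucleotide position: the number of events applied along a branch is
Poisson with mean ``branch_length × len(cds)`` (an exact-count mode is
available for tests).  Rejected proposals (stop-creating, or replacements
vetoed by selection) do not consume branch length.

Every accepted event can be classified against the sequon census: loss via
the target (Asn) codon, via the recognition (Ser/Thr) codon or via a
middle→Pro change, and gains by the mirror-image paths.  A single event
may log both a gain and a loss (in overlapping windows); both are
recorded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genetic_code import (
    ASN_BLOCK,
    NUCLEOTIDES,
    SER_THR_BLOCK,
    CodonTable,
    InputError,
    codon_neighbors,
)

_TABLE = CodonTable.standard()

# integer encodings: nt 0..3 = ACGT, codon index = 16*a + 4*b + c
_NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}
_ALL_CODONS = ["".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)]


def _codon_index(codon: str) -> int:
    return (_NT_INDEX[codon[0]] * 16 + _NT_INDEX[codon[1]] * 4
            + _NT_INDEX[codon[2]])


_IS_STOP = np.zeros(64, dtype=bool)
_AA_IDX = np.zeros(64, dtype=np.int8)
_IS_ASN = np.zeros(64, dtype=bool)
_IS_ST = np.zeros(64, dtype=bool)
_IS_PRO = np.zeros(64, dtype=bool)
_aa_codes: Dict[str, int] = {}
for _c in _ALL_CODONS:
    _i = _codon_index(_c)
    _aa = _TABLE.codon_to_aa[_c]
    _IS_STOP[_i] = _aa == "*"
    _AA_IDX[_i] = _aa_codes.setdefault(_aa, len(_aa_codes))
    _IS_ASN[_i] = _c in ASN_BLOCK
    _IS_ST[_i] = _c in SER_THR_BLOCK
    _IS_PRO[_i] = _aa == "P"

# NEW_CODON[codon, offset, nt] = codon index after writing nt at offset
_NEW_CODON = np.zeros((64, 3, 4), dtype=np.int8)
for _i in range(64):
    for _off, _mul in ((0, 16), (1, 4), (2, 1)):
        _digit = (_i // _mul) % 4
        for _nt in range(4):
            _NEW_CODON[_i, _off, _nt] = _i + (_nt - _digit) * _mul


def _encode(cds: str) -> np.ndarray:
    cds = cds.upper()
    if len(cds) % 3:
        raise InputError("CDS length not divisible by 3")
    try:
        seq = np.array([_NT_INDEX[n] for n in cds], dtype=np.int8)
    except KeyError as exc:
        raise InputError(f"invalid nucleotide {exc.args[0]!r}") from exc
    codons = seq[0::3].astype(np.int16) * 16 + seq[1::3] * 4 + seq[2::3]
    if _IS_STOP[codons].any():
        raise InputError("internal stop codon in CDS")
    return seq


def _decode(seq: np.ndarray) -> str:
    return "".join(NUCLEOTIDES[i] for i in seq)


@dataclass(frozen=True)
class SimParams:
    """Settings for one mutagenesis run.

    branch_length
        Expected accepted substitutions per nucleotide position.
    replacement_acceptance
        Probability that a nonsynonymous proposal is accepted
        (1.0 = strictly neutral; synonymous proposals are always accepted).
    exact_events
        When set, apply exactly this many events instead of drawing a
        Poisson count (test hook).
    """

    branch_length: float = 1.0
    replacement_acceptance: float = 1.0
    seed: int = 0
    replicates: int = 1
    exact_events: Optional[int] = None

    def __post_init__(self) -> None:
        if self.branch_length < 0:
            raise InputError("branch_length must be >= 0")
        if not 0.0 <= self.replacement_acceptance <= 1.0:
            raise InputError("replacement_acceptance must be in [0, 1]")
        if self.replicates < 1:
            raise InputError("replicates must be >= 1")


@dataclass(frozen=True)
class SimTrajectory:
    """An ordered substitution log; replaying it regenerates the end CDS."""

    start_cds: str
    end_cds: str
    events: Tuple[Tuple[int, str, str], ...]  # (0-based nt pos, from, to)

    def replay(self) -> str:
        seq = list(self.start_cds)
        for pos, old, new in self.events:
            if seq[pos] != old:
                raise InputError("trajectory does not replay from its start")
            seq[pos] = new
        return "".join(seq)


_CHUNK = 4096


def evolve(cds: str, params: SimParams, replicate: int = 0) -> SimTrajectory:
    """Run one replicate of serial mutagenesis on ``cds``.

    Deterministic given (seed, replicate): the replicate index is folded
    into the seed stream.
    """
    seq = _encode(cds)
    L = len(seq)
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=params.seed, spawn_key=(replicate,)))
    codons = (seq[0::3].astype(np.int16) * 16 + seq[1::3] * 4
              + seq[2::3]).astype(np.int8)

    if params.exact_events is not None:
        n_target = int(params.exact_events)
    else:
        n_target = int(rng.poisson(params.branch_length * L))

    events: List[Tuple[int, str, str]] = []
    accept = params.replacement_acceptance
    proposals = 0
    limit = 1000 * (n_target + 10) * max(1, int(1 / max(accept, 1e-3)))
    while len(events) < n_target:
        pos = rng.integers(0, L, size=_CHUNK)
        alt = rng.integers(0, 3, size=_CHUNK)
        u = rng.random(size=_CHUNK) if accept < 1.0 else None
        for k in range(_CHUNK):
            proposals += 1
            if proposals > limit:
                raise InputError("mutagenesis failed to accept enough events")
            p = int(pos[k])
            old_nt = int(seq[p])
            new_nt = int(alt[k])
            if new_nt >= old_nt:
                new_nt += 1
            ci = p // 3
            new_codon = _NEW_CODON[codons[ci], p % 3, new_nt]
            if _IS_STOP[new_codon]:
                continue
            if accept < 1.0 and _AA_IDX[new_codon] != _AA_IDX[codons[ci]]:
                if u[k] > accept:
                    continue
            seq[p] = new_nt
            codons[ci] = new_codon
            events.append((p, NUCLEOTIDES[old_nt], NUCLEOTIDES[new_nt]))
            if len(events) >= n_target:
                break
    return SimTrajectory(start_cds=cds.upper(), end_cds=_decode(seq),
                         events=tuple(events))


# ---------------------------------------------------------------------------
# Event classification


@dataclass
class EventTally:
    """Gain/loss counts by mutational path class."""

    loss_target: int = 0
    loss_middle: int = 0
    loss_recognition: int = 0
    gain_target: int = 0
    gain_middle: int = 0
    gain_recognition: int = 0

    @property
    def losses(self) -> int:
        return self.loss_target + self.loss_middle + self.loss_recognition

    @property
    def gains(self) -> int:
        return self.gain_target + self.gain_middle + self.gain_recognition

    def __iadd__(self, other: "EventTally") -> "EventTally":
        for f in ("loss_target", "loss_middle", "loss_recognition",
                  "gain_target", "gain_middle", "gain_recognition"):
            setattr(self, f, getattr(self, f) + getattr(other, f))
        return self


_PATH_NAMES = ("target", "middle", "recognition")


def _window_is_site(codons: np.ndarray, w: int) -> bool:
    return bool(_IS_ASN[codons[w]] and not _IS_PRO[codons[w + 1]]
                and _IS_ST[codons[w + 2]])


def classify_events(trajectory: SimTrajectory) -> EventTally:
    """Attribute every census-changing event of a trajectory to a path class.

    The trajectory is replayed; for each substitution, the (up to three)
    windows containing the changed codon are compared before and after.
    The path class is the changed codon's position within the window:
    target (first), middle, or recognition (third).
    """
    seq = _encode(trajectory.start_cds)
    codons = (seq[0::3].astype(np.int16) * 16 + seq[1::3] * 4
              + seq[2::3]).astype(np.int8)
    ncod = len(codons)
    tally = EventTally()
    for pos, old, new in trajectory.events:
        ci = pos // 3
        windows = [w for w in (ci - 2, ci - 1, ci) if 0 <= w <= ncod - 3]
        before = [_window_is_site(codons, w) for w in windows]
        new_codon = _NEW_CODON[codons[ci], pos % 3, _NT_INDEX[new]]
        seq[pos] = _NT_INDEX[new]
        codons[ci] = new_codon
        for w, was in zip(windows, before):
            now = _window_is_site(codons, w)
            if was == now:
                continue
            path = _PATH_NAMES[ci - w]
            kind = "loss" if was else "gain"
            attr = f"{kind}_{path}"
            setattr(tally, attr, getattr(tally, attr) + 1)
    if _decode(seq) != trajectory.end_cds:
        raise InputError("trajectory does not replay to its recorded end")
    return tally


def simulate_panel(records, params: SimParams):
    """Per-replicate gain/loss tallies for a panel of CDS records.

    Returns a pandas DataFrame with one row per (record, replicate):
    event count, path-classified gains and losses, the analytic gain
    potential, and start-sequence covariates (site count, A content,
    Asn and Ser+Thr fractions).  Replicate seeds are folded from
    ``params.seed`` deterministically.
    """
    import pandas as pd

    from .scan import find_sites

    rows = []
    for idx, rec in enumerate(records):
        cds = rec.cds if hasattr(rec, "cds") else rec
        protein = _TABLE.translate(cds)
        pot = gain_potential(cds)
        n_sites = len(find_sites(protein))
        a_frac = cds.count("A") / len(cds)
        asn_frac = protein.count("N") / len(protein)
        st_frac = (protein.count("S") + protein.count("T")) / len(protein)
        expected_events = (params.exact_events if params.exact_events is not None
                           else params.branch_length * len(cds))
        rec_id = getattr(rec, "id", f"seq{idx}")
        for rep in range(params.replicates):
            traj = evolve(cds, params, replicate=idx * 100000 + rep)
            tally = classify_events(traj)
            rows.append({
                "id": rec_id, "replicate": rep, "events": len(traj.events),
                "start_sites": n_sites, "a_content": a_frac,
                "asn_fraction": asn_frac, "ser_thr_fraction": st_frac,
                "gain_potential": pot,
                "expected_gains": pot * expected_events,
                "gains": tally.gains, "losses": tally.losses,
                "loss_target": tally.loss_target,
                "loss_middle": tally.loss_middle,
                "loss_recognition": tally.loss_recognition,
                "gain_target": tally.gain_target,
                "gain_middle": tally.gain_middle,
                "gain_recognition": tally.gain_recognition,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Analytic gain potential

# creating substitutions per near-site class, per codon identity
_PATHS_INTO_ASN = {c: frozenset(n for n in codon_neighbors(c) if n in ASN_BLOCK)
                   for c in _ALL_CODONS}
_PATHS_INTO_ST = {c: frozenset(n for n in codon_neighbors(c)
                               if n in SER_THR_BLOCK)
                  for c in _ALL_CODONS}
_PRO_EXITS = {c: frozenset(n for n in codon_neighbors(c)
                           if not _IS_PRO[_codon_index(n)]
                           and n not in _TABLE.stops)
              for c in _ALL_CODONS if _IS_PRO[_codon_index(c)]}


def gain_potential(cds: str) -> float:
    """Probability that one accepted neutral substitution creates a site.

    Computed analytically from the near-site census: each near-site window
    contributes its substitution paths into the motif, distinct proposals
    are pooled (a Pro codon shared by an N.P.S/T and an N.X.X_S/T window
    would otherwise be double-counted), and the total is divided by the
    number of proposals that do not create an in-frame stop (the
    denominator of the neutral acceptance process).  Multiplying by the
    number of accepted events gives the expected gain count at the start
    census; no simulation is involved.
    """
    from .scan import find_near_sites  # local import to avoid a cycle

    cds = cds.upper()
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    creating = set()  # distinct (codon position, replacement codon) proposals
    for pos, cls in find_near_sites(cds):
        w = pos - 1
        if cls == "X_N.X.S/T":
            creating.update((w, n) for n in _PATHS_INTO_ASN[codons[w]])
        elif cls == "N.X.X_S/T":
            creating.update((w + 2, n) for n in _PATHS_INTO_ST[codons[w + 2]])
        else:  # N.P.S/T: any Pro -> non-Pro sense change in the middle
            creating.update((w + 1, n) for n in _PRO_EXITS[codons[w + 1]])
    stop_proposals = sum(
        1 for c in codons for n in codon_neighbors(c) if n in _TABLE.stops
    )
    total = 9 * len(codons) - stop_proposals
    return len(creating) / total if total else 0.0


def creating_proposals(cds: str) -> int:
    """Brute-force count of single substitutions of ``cds`` creating a site.

    Exhaustive scan over all 3L proposals; the independent oracle for
    :func:`gain_potential`.
    """
    from .scan import find_sites

    cds = cds.upper()
    base_sites = set(find_sites(_TABLE.translate(cds)))
    count = 0
    for p in range(len(cds)):
        for nt in NUCLEOTIDES:
            if nt == cds[p]:
                continue
            mutant = cds[:p] + nt + cds[p + 1:]
            ci = p // 3
            if mutant[3 * ci:3 * ci + 3] in _TABLE.stops:
                continue
            if set(find_sites(_TABLE.translate(mutant))) - base_sites:
                count += 1
    return count
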