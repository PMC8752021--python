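"""Monte-Carlo RNA-pool simulator on a toroidal grid.

The world is a square torus of "rooms", each holding raw-material precursors,
free nucleotides (counts per base A/U/C/G) and RNA molecules.  A nucleotide
synthetase ribozyme (NSR) is any molecule whose sequence contains the NSR
motif; in rooms holding a functional NSR, precursors turn into nucleotides at
the catalyzed probability ``PNFR`` instead of the spontaneous ``PNF`` —
catalysis is local, which is what lets the NSR favor its own replication.  A
control (Ctrl) motif of the same length identifies a species with no
catalytic activity, and a knockout flag strips NSRs of function while leaving
their identity intact (the over-fitting control).

Eight per-step event probabilities drive the dynamics and are the targets of
automatic exploration:

========  ==========================================================
``PNF``   non-enzymatic nucleotide formation, per precursor
``PNFR``  NSR-catalyzed formation (replaces ``PNF`` in catalyzed rooms)
``PND``   free-nucleotide decay back to precursor
``PRL``   random ligation, per randomly paired molecule pair per room
``PBB``   bond breaking, per internal phosphodiester bond
``PAT``   template-directed attachment of the next nucleotide
``PFP``   false pairing, given an attachment
``PMV``   movement to an adjacent room, per molecule
========  ==========================================================

Events fire in a fixed order each step — formation, decay, ligation, end
decay, bond breaking, template-directed synthesis, movement — so that
material-producing events precede their consumers and trajectories are
deterministic under a fixed random stream.  End decay (a fixed world
constant, not an exploration target) erodes one terminal residue per event
back into the free pool — the nascent strand first in a duplex, so a stalled
copy eventually aborts and frees its template; without a degradation channel
molecules would be immortal and no species could ever decline.

Total material (precursors + free nucleotides + all strand residues) is
exactly conserved between inoculations.

The inner loop is a numba kernel over fixed-width ``uint8`` sequence arrays
(maximum strand length 48; a ligation whose product would exceed the cap
simply does not fire).  The :class:`Molecule` view objects are materialized
on demand and are the public face of the state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .parameters import ParameterDef, ParameterSet

__all__ = [
    "BASES",
    "L_MAX",
    "NSRParams",
    "NSRWorldConfig",
    "Molecule",
    "NSRWorld",
    "parameter_defs",
    "init_world",
    "inoculate",
    "is_nsr",
    "is_ctrl",
    "is_functional",
    "complement",
    "step",
    "run",
    "save_snapshot",
    "load_snapshot",
]

BASES = "AUCG"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# Watson-Crick pairing: A<->U, C<->G; with this base order the complement
# index is the bitwise XOR with 1.
_COMPLEMENT = str.maketrans("AUCG", "UAGC")

#: Maximum strand length representable by the fixed-width state arrays.
L_MAX = 48

#: Default exploration starting values (the unfavorable parameter set under
#: which an inoculated NSR population declines instead of spreading).
_DEFAULT_INITIALS = {
    "PNF": 4e-3,
    "PNFR": 0.02,
    "PND": 1e-3,
    "PRL": 2e-5,
    "PBB": 1e-5,
    "PAT": 0.5,
    "PFP": 0.1,
    "PMV": 1e-3,
}

_DESCRIPTIONS = {
    "PNF": "non-enzymatic nucleotide formation probability per precursor per step",
    "PNFR": "NSR-catalyzed nucleotide formation probability (replaces PNF locally)",
    "PND": "free-nucleotide decay probability per nucleotide per step",
    "PRL": "random ligation probability per paired molecule pair per step",
    "PBB": "bond breaking probability per internal bond per step",
    "PAT": "template-directed nucleotide attachment probability per molecule per step",
    "PFP": "false pairing probability given an attachment",
    "PMV": "movement probability to an adjacent room per molecule per step",
}

PARAM_NAMES = tuple(_DEFAULT_INITIALS)


def parameter_defs(initials: dict[str, float] | None = None) -> tuple[ParameterDef, ...]:
    """The eight explorable probabilities, optionally re-anchored."""
    vals = dict(_DEFAULT_INITIALS)
    if initials:
        unknown = set(initials) - set(vals)
        if unknown:
            raise ValueError(f"unknown NSR parameters: {sorted(unknown)}")
        vals.update(initials)
    return tuple(
        ParameterDef(name=n, initial=vals[n], kind="probability", description=_DESCRIPTIONS[n])
        for n in PARAM_NAMES
    )


@dataclass(frozen=True)
class NSRParams:
    """The eight explored event probabilities."""

    PNF: float
    PNFR: float
    PND: float
    PRL: float
    PBB: float
    PAT: float
    PFP: float
    PMV: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v} outside [0, 1]")

    @classmethod
    def from_parameter_set(cls, params: ParameterSet) -> "NSRParams":
        return cls(**{n: params[n] for n in PARAM_NAMES})


@dataclass(frozen=True)
class NSRWorldConfig:
    """World geometry, material budget and species motifs.

    These are the model constants held fixed during exploration.  The
    default sizes make the characteristic dynamics (spread or decline of an
    inoculated species) visible at full scale; :meth:`small` gives the
    desk-scale twin used throughout the test suite, with a faster
    ``end_decay`` matching its ~50x compressed timescale.
    """

    grid_side: int = 30
    total_material: int = 40_000
    nsr_motif: str = "AUGCCGUAAC"
    ctrl_motif: str = "GACUUAGCAU"
    duplex_separation: float = 0.5
    end_decay: float = 0.001
    knockout: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_side < 2:
            raise ValueError("grid_side must be >= 2")
        if self.total_material < 1:
            raise ValueError("total_material must be >= 1")
        if len(self.nsr_motif) != len(self.ctrl_motif):
            raise ValueError("NSR and control motifs must have equal length")
        if self.nsr_motif == self.ctrl_motif:
            raise ValueError("NSR and control motifs must differ")
        for motif in (self.nsr_motif, self.ctrl_motif):
            if not motif or any(b not in BASES for b in motif):
                raise ValueError(f"motif {motif!r} must be non-empty over {BASES}")
            if len(motif) > L_MAX:
                raise ValueError(f"motif longer than the {L_MAX}-residue cap")

    @classmethod
    def small(cls, **overrides) -> "NSRWorldConfig":
        """Desk-scale configuration (10x10 grid, 4000 material units)."""
        merged = {"grid_side": 10, "total_material": 4_000, "end_decay": 0.004, **overrides}
        return cls(**merged)

    @property
    def n_rooms(self) -> int:
        return self.grid_side * self.grid_side


class Molecule:
    """One RNA strand, optionally carrying a nascent complementary strand.

    ``nascent`` is the contiguous filled prefix of the growing complement
    (stored as the literal bases of the new strand); while present the
    molecule is a duplex: its template is protected from breaking and end
    decay and excluded from ligation.
    """

    __slots__ = ("room", "seq", "nascent")

    def __init__(self, room: int, seq: str, nascent: str | None = None):
        self.room = room
        self.seq = seq
        self.nascent = nascent

    def __repr__(self) -> str:  # pragma: no cover
        return f"Molecule(room={self.room}, seq={self.seq!r}, nascent={self.nascent!r})"


def complement(seq: str) -> str:
    """Watson-Crick complement, position by position."""
    return seq.translate(_COMPLEMENT)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode().translate(_ENC_TABLE), dtype=np.uint8).copy()


_ENC_TABLE = bytes.maketrans(b"AUCG", bytes([0, 1, 2, 3]))
_DEC_TABLE = bytes.maketrans(bytes([0, 1, 2, 3]), b"AUCG")


def _decode(row: np.ndarray, length: int) -> str:
    return row[:length].tobytes().translate(_DEC_TABLE).decode()


@dataclass
class NSRWorld:
    """Full state of the RNA pool (array-of-structs molecule storage).

    ``material_ledger`` is the conserved total: the initial material plus
    everything added exogenously by inoculations.
    """

    config: NSRWorldConfig
    precursors: np.ndarray  # (n_rooms,) int64
    free: np.ndarray  # (n_rooms, 4) int64, per-base free nucleotides
    seqs: np.ndarray  # (cap, L_MAX) uint8
    slen: np.ndarray  # (cap,) int64 template lengths
    nasc: np.ndarray  # (cap, L_MAX) uint8
    nlen: np.ndarray  # (cap,) int64 nascent lengths (0 = single-stranded)
    mol_room: np.ndarray  # (cap,) int64
    alive: np.ndarray  # (cap,) bool
    nsr_flag: np.ndarray  # (cap,) bool: template contains the NSR motif
    ctrl_flag: np.ndarray  # (cap,) bool
    freelist: np.ndarray  # (cap,) int64 stack of free slots
    free_top: np.ndarray  # (1,) int64 stack size
    material_ledger: int = 0
    step_count: int = 0

    # -- views ---------------------------------------------------------------

    @property
    def molecules(self) -> list[Molecule]:
        """Materialized molecule views, in stable slot order."""
        out = []
        for i in np.nonzero(self.alive)[0]:
            nascent = _decode(self.nasc[i], int(self.nlen[i])) if self.nlen[i] else None
            out.append(Molecule(int(self.mol_room[i]), _decode(self.seqs[i], int(self.slen[i])), nascent))
        return out

    def current_material(self) -> int:
        strands = int(self.slen[self.alive].sum() + self.nlen[self.alive].sum())
        return int(self.precursors.sum() + self.free.sum()) + strands

    def count_motif(self, motif: str) -> int:
        """Template strands containing ``motif`` (duplex-bound included).

        A strand busy templating its complement still exists as a molecule;
        nascent strands are never counted (they are different molecules in
        the making).
        """
        if motif == self.config.nsr_motif:
            return int(np.count_nonzero(self.nsr_flag & self.alive))
        if motif == self.config.ctrl_motif:
            return int(np.count_nonzero(self.ctrl_flag & self.alive))
        return sum(1 for m in self.molecules if motif in m.seq)

    def check_conservation(self) -> None:
        current = self.current_material()
        if current != self.material_ledger:
            raise AssertionError(
                f"material leak at step {self.step_count}: "
                f"{current} != ledger {self.material_ledger}"
            )

    # -- mutation helpers ----------------------------------------------------

    def _ensure_capacity(self, needed: int) -> None:
        cap = self.seqs.shape[0]
        if needed <= cap:
            return
        extra = needed - cap
        self.seqs = np.vstack([self.seqs, np.zeros((extra, L_MAX), np.uint8)])
        self.nasc = np.vstack([self.nasc, np.zeros((extra, L_MAX), np.uint8)])
        for name in ("slen", "nlen", "mol_room"):
            setattr(self, name, np.concatenate([getattr(self, name), np.zeros(extra, np.int64)]))
        for name in ("alive", "nsr_flag", "ctrl_flag"):
            setattr(self, name, np.concatenate([getattr(self, name), np.zeros(extra, bool)]))
        self.freelist = np.concatenate([self.freelist, np.zeros(extra, np.int64)])
        top = int(self.free_top[0])
        self.freelist[top : top + extra] = np.arange(cap, needed)
        self.free_top[0] = top + extra

    def add_molecule(self, room: int, seq: str, nascent: str | None = None) -> None:
        """Place one molecule; material must already be on the ledger."""
        if not 1 <= len(seq) <= L_MAX or (nascent and len(nascent) > len(seq)):
            raise ValueError("sequence length outside representable range")
        self._ensure_capacity(int(self.alive.sum()) + 1 + 8)
        top = int(self.free_top[0])
        slot = int(self.freelist[top - 1])
        self.free_top[0] = top - 1
        self.slen[slot] = len(seq)
        self.seqs[slot, : len(seq)] = _encode(seq)
        if nascent:
            self.nlen[slot] = len(nascent)
            self.nasc[slot, : len(nascent)] = _encode(nascent)
        else:
            self.nlen[slot] = 0
        self.mol_room[slot] = room
        self.alive[slot] = True
        self.nsr_flag[slot] = self.config.nsr_motif in seq
        self.ctrl_flag[slot] = self.config.ctrl_motif in seq


def init_world(config: NSRWorldConfig) -> NSRWorld:
    """All material starts as precursors, split uniformly across rooms."""
    n = config.n_rooms
    base, rem = divmod(config.total_material, n)
    pre = np.full(n, base, dtype=np.int64)
    pre[:rem] += 1
    cap = config.total_material // 2 + 16
    return NSRWorld(
        config=config,
        precursors=pre,
        free=np.zeros((n, 4), dtype=np.int64),
        seqs=np.zeros((cap, L_MAX), np.uint8),
        slen=np.zeros(cap, np.int64),
        nasc=np.zeros((cap, L_MAX), np.uint8),
        nlen=np.zeros(cap, np.int64),
        mol_room=np.zeros(cap, np.int64),
        alive=np.zeros(cap, bool),
        nsr_flag=np.zeros(cap, bool),
        ctrl_flag=np.zeros(cap, bool),
        freelist=np.arange(cap - 1, -1, -1, dtype=np.int64),
        free_top=np.array([cap], np.int64),
        material_ledger=config.total_material,
    )


def inoculate(
    world: NSRWorld, species: str, copies: int, rng: np.random.Generator
) -> NSRWorld:
    """Drop ``copies`` exact-motif molecules into uniformly random rooms.

    Inoculated material is exogenous: it is added to the conservation
    ledger rather than drawn from the pool.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    if species == "nsr":
        motif = world.config.nsr_motif
    elif species == "ctrl":
        motif = world.config.ctrl_motif
    else:
        raise ValueError(f"unknown species {species!r}")
    rooms = rng.integers(0, world.config.n_rooms, size=copies)
    world.material_ledger += copies * len(motif)
    world._ensure_capacity(world.material_ledger // 2 + 16)
    for r in rooms:
        world.add_molecule(int(r), motif)
    return world


def is_nsr(molecule: Molecule, config: NSRWorldConfig) -> bool:
    """True iff the template sequence contains the NSR motif.

    The motif's complement is a different molecule and does not count; a
    full replication cycle (template -> complement -> complement of the
    complement) is needed to regenerate a countable NSR.
    """
    return config.nsr_motif in molecule.seq


def is_ctrl(molecule: Molecule, config: NSRWorldConfig) -> bool:
    return config.ctrl_motif in molecule.seq


def is_functional(molecule: Molecule, config: NSRWorldConfig) -> bool:
    """Catalytic competence: NSR identity minus the knockout flag."""
    return (not config.knockout) and is_nsr(molecule, config)


# ---------------------------------------------------------------------------
# numba kernel


@njit(cache=True, inline="always")
def _contains(seqs, i, length, motif):
    m = motif.shape[0]
    for start in range(length - m + 1):
        ok = True
        for k in range(m):
            if seqs[i, start + k] != motif[k]:
                ok = False
                break
        if ok:
            return True
    return False


@njit(cache=True, inline="always")
def _kill(i, alive, freelist, free_top):
    alive[i] = False
    freelist[free_top[0]] = i
    free_top[0] += 1


@njit(cache=True, inline="always")
def _spawn(room_idx, alive, freelist, free_top, slen, nlen, mol_room):
    if free_top[0] == 0:
        return -1
    slot = freelist[free_top[0] - 1]
    free_top[0] -= 1
    alive[slot] = True
    slen[slot] = 0
    nlen[slot] = 0
    mol_room[slot] = room_idx
    return slot


@njit(cache=True)
def _step_kernel(
    pre, free, seqs, slen, nasc, nlen, mol_room, alive, nsr_flag, ctrl_flag,
    freelist, free_top, nsr_motif, ctrl_motif,
    PNF, PNFR, PND, PRL, PBB, PAT, PFP, PMV,
    sep, end_decay, knockout, side, seed,
):
    np.random.seed(seed)
    n_rooms = pre.shape[0]
    cap = seqs.shape[0]

    # (1) nucleotide formation: catalyzed rooms use PNFR instead of PNF
    if PNF > 0.0 or PNFR > 0.0:
        func = np.zeros(n_rooms, np.bool_)
        if PNFR != PNF and not knockout:
            for i in range(cap):
                if alive[i] and nsr_flag[i]:
                    func[mol_room[i]] = True
        for r in range(n_rooms):
            p = PNFR if func[r] else PNF
            if p > 0.0 and pre[r] > 0:
                k = np.random.binomial(pre[r], p)
                pre[r] -= k
                for _ in range(k):
                    free[r, np.random.randint(0, 4)] += 1

    # (2) free-nucleotide decay
    if PND > 0.0:
        for r in range(n_rooms):
            for b in range(4):
                if free[r, b] > 0:
                    k = np.random.binomial(free[r, b], PND)
                    free[r, b] -= k
                    pre[r] += k

    # (3) random ligation (free nucleotides are length-1 molecules here).
    # Sampling 2K distinct entities uniformly and pairing them consecutively
    # is distributionally identical to a full random disjoint pairing in
    # which K pairs fired.
    if PRL > 0.0:
        npoly = np.zeros(n_rooms, np.int64)
        for i in range(cap):
            if alive[i] and nlen[i] == 0:
                npoly[mol_room[i]] += 1
        for r in range(n_rooms):
            ft = free[r, 0] + free[r, 1] + free[r, 2] + free[r, 3]
            m = ft + npoly[r]
            if m < 2:
                continue
            n_lig = np.random.binomial(m // 2, PRL)
            if n_lig == 0:
                continue
            ents = np.empty(m, np.int64)
            idx = 0
            for b in range(4):
                for _ in range(free[r, b]):
                    ents[idx] = b
                    idx += 1
            for i in range(cap):
                if alive[i] and nlen[i] == 0 and mol_room[i] == r:
                    ents[idx] = 4 + i
                    idx += 1
            take = 2 * n_lig
            for t in range(take):
                j = t + np.random.randint(0, m - t)
                tmp = ents[t]
                ents[t] = ents[j]
                ents[j] = tmp
            for k2 in range(n_lig):
                a = ents[2 * k2]
                b2 = ents[2 * k2 + 1]
                la = 1 if a < 4 else slen[a - 4]
                lb = 1 if b2 < 4 else slen[b2 - 4]
                if la + lb > L_MAX:
                    continue  # product would exceed the cap: no event
                buf = np.empty(la + lb, np.uint8)
                if a < 4:
                    buf[0] = a
                    free[r, a] -= 1
                else:
                    for k in range(la):
                        buf[k] = seqs[a - 4, k]
                    _kill(a - 4, alive, freelist, free_top)
                if b2 < 4:
                    buf[la] = b2
                    free[r, b2] -= 1
                else:
                    for k in range(lb):
                        buf[la + k] = seqs[b2 - 4, k]
                    _kill(b2 - 4, alive, freelist, free_top)
                s = _spawn(r, alive, freelist, free_top, slen, nlen, mol_room)
                if s < 0:
                    # no slot: return residues to the pool (cannot happen
                    # with the ledger-derived capacity, but stay safe)
                    for k in range(la + lb):
                        free[r, buf[k]] += 1
                    continue
                slen[s] = la + lb
                for k in range(la + lb):
                    seqs[s, k] = buf[k]
                nsr_flag[s] = _contains(seqs, s, la + lb, nsr_motif)
                ctrl_flag[s] = _contains(seqs, s, la + lb, ctrl_motif)

    # (4a) end decay: one terminal residue back to the pool; nascent first
    if end_decay > 0.0:
        for i in range(cap):
            if not alive[i]:
                continue
            if np.random.random() < end_decay:
                r = mol_room[i]
                if nlen[i] > 0:
                    free[r, nasc[i, nlen[i] - 1]] += 1
                    nlen[i] -= 1
                else:
                    free[r, seqs[i, slen[i] - 1]] += 1
                    slen[i] -= 1
                    if slen[i] == 1:
                        free[r, seqs[i, 0]] += 1
                        slen[i] = 0
                    if slen[i] == 0:
                        _kill(i, alive, freelist, free_top)
                    else:
                        nsr_flag[i] = _contains(seqs, i, slen[i], nsr_motif)
                        ctrl_flag[i] = _contains(seqs, i, slen[i], ctrl_motif)

    # (4b) bond breaking (single strands only; duplexes are protected)
    if PBB > 0.0:
        for i in range(cap):
            if not (alive[i] and nlen[i] == 0 and slen[i] > 1):
                continue
            n_bonds = slen[i] - 1
            k = np.random.binomial(n_bonds, PBB)
            if k == 0:
                continue
            # choose k distinct cut bonds via partial shuffle
            bonds = np.arange(1, slen[i])
            for t in range(k):
                j = t + np.random.randint(0, n_bonds - t)
                tmp = bonds[t]
                bonds[t] = bonds[j]
                bonds[j] = tmp
            cuts = np.sort(bonds[:k])
            r = mol_room[i]
            total = slen[i]
            start = cuts[0]
            # fragments after the first cut become new molecules (or pool)
            for c in range(k + 1):
                lo = 0 if c == 0 else cuts[c - 1]
                hi = cuts[c] if c < k else total
                if c == 0:
                    continue  # first fragment stays in slot i, handled below
                flen = hi - lo
                if flen == 1:
                    free[r, seqs[i, lo]] += 1
                else:
                    s = _spawn(r, alive, freelist, free_top, slen, nlen, mol_room)
                    if s < 0:
                        for k3 in range(lo, hi):
                            free[r, seqs[i, k3]] += 1
                        continue
                    slen[s] = flen
                    for k3 in range(flen):
                        seqs[s, k3] = seqs[i, lo + k3]
                    nsr_flag[s] = _contains(seqs, s, flen, nsr_motif)
                    ctrl_flag[s] = _contains(seqs, s, flen, ctrl_motif)
            # shrink the original to its first fragment
            if start == 1:
                free[r, seqs[i, 0]] += 1
                _kill(i, alive, freelist, free_top)
            else:
                slen[i] = start
                nsr_flag[i] = _contains(seqs, i, start, nsr_motif)
                ctrl_flag[i] = _contains(seqs, i, start, ctrl_motif)

    # (5) template-directed synthesis: complete duplexes may separate, then
    # molecules extend their nascent strand by one drawn nucleotide
    if sep > 0.0:
        for i in range(cap):
            if alive[i] and nlen[i] > 0 and nlen[i] == slen[i]:
                if np.random.random() < sep:
                    s = _spawn(mol_room[i], alive, freelist, free_top, slen, nlen, mol_room)
                    if s >= 0:
                        L = nlen[i]
                        slen[s] = L
                        for k in range(L):
                            seqs[s, k] = nasc[i, k]
                        nsr_flag[s] = _contains(seqs, s, L, nsr_motif)
                        ctrl_flag[s] = _contains(seqs, s, L, ctrl_motif)
                        nlen[i] = 0
    if PAT > 0.0:
        for i in range(cap):
            if not alive[i] or np.random.random() >= PAT:
                continue
            pos = nlen[i]
            if pos >= slen[i]:
                continue  # complete duplex awaiting separation
            r = mol_room[i]
            base = seqs[i, pos] ^ 1  # Watson-Crick complement
            if PFP > 0.0 and np.random.random() < PFP:
                base = (base + 1 + np.random.randint(0, 3)) % 4
            if free[r, base] > 0:
                free[r, base] -= 1
                nasc[i, pos] = base
                nlen[i] = pos + 1

    # (6) movement to a uniformly random von Neumann neighbor
    if PMV > 0.0:
        for i in range(cap):
            if alive[i] and np.random.random() < PMV:
                row = mol_room[i] // side
                col = mol_room[i] % side
                d = np.random.randint(0, 4)
                if d == 0:
                    row = (row + 1) % side
                elif d == 1:
                    row = (row - 1) % side
                elif d == 2:
                    col = (col + 1) % side
                else:
                    col = (col - 1) % side
                mol_room[i] = row * side + col


def step(world: NSRWorld, params: NSRParams, rng: np.random.Generator) -> NSRWorld:
    """Advance the world by one Monte-Carlo step (fixed event order).

    The kernel's random stream is seeded per call from ``rng``, so a run is
    fully determined by the caller's generator state.
    """
    cfg = world.config
    _step_kernel(
        world.precursors, world.free, world.seqs, world.slen, world.nasc,
        world.nlen, world.mol_room, world.alive, world.nsr_flag,
        world.ctrl_flag, world.freelist, world.free_top,
        _encode(cfg.nsr_motif), _encode(cfg.ctrl_motif),
        params.PNF, params.PNFR, params.PND, params.PRL, params.PBB,
        params.PAT, params.PFP, params.PMV,
        cfg.duplex_separation, cfg.end_decay, cfg.knockout, cfg.grid_side,
        int(rng.integers(0, 2**31 - 1)),
    )
    world.step_count += 1
    return world


def run(
    world: NSRWorld,
    params: NSRParams,
    n_steps: int,
    *,
    inoculations: Sequence = (),
    rng: np.random.Generator,
    record_every: int = 1000,
    check_conservation: bool = True,
):
    """Run ``n_steps`` steps, applying scheduled inoculations.

    An inoculation "at step S" fires before step S's events (0-based);
    ``S == n_steps`` fires after the final step.  Returns a DataFrame with
    one row per recorded step: step, nsr, ctrl, molecules, free_nt,
    precursors.  Conservation is checked at every recorded step.
    """
    import pandas as pd

    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    schedule: dict[int, list] = {}
    for ino in inoculations:
        if ino.step > n_steps:
            raise ValueError(
                f"inoculation at step {ino.step} scheduled after the run ({n_steps} steps)"
            )
        schedule.setdefault(int(ino.step), []).append(ino)

    cfg = world.config
    rows = []

    def _record(s: int) -> None:
        if check_conservation:
            world.check_conservation()
        rows.append(
            (
                s,
                world.count_motif(cfg.nsr_motif),
                world.count_motif(cfg.ctrl_motif),
                int(world.alive.sum()),
                int(world.free.sum()),
                int(world.precursors.sum()),
            )
        )

    _record(0)
    for s in range(n_steps):
        for ino in schedule.get(s, ()):
            inoculate(world, ino.species, ino.copies, rng)
        step(world, params, rng)
        t = s + 1
        if t % record_every == 0 or t == n_steps:
            _record(t)
    for ino in schedule.get(n_steps, ()):
        inoculate(world, ino.species, ino.copies, rng)
    return pd.DataFrame(
        rows, columns=["step", "nsr", "ctrl", "molecules", "free_nt", "precursors"]
    )


# ---------------------------------------------------------------------------
# plain-text snapshots


def save_snapshot(world: NSRWorld, path) -> None:
    """Write the world to a plain-text snapshot.

    Format: header lines ``#ledger``, ``#step``, ``#precursors`` (space-
    separated per room) and ``#free`` (four counts per room, rooms separated
    by ``;``), then one molecule per line:
    ``room<TAB>sequence<TAB>nascent-prefix`` (``-`` for no nascent strand).
    """
    lines = [
        f"#ledger\t{world.material_ledger}",
        f"#step\t{world.step_count}",
        "#precursors\t" + " ".join(map(str, world.precursors.tolist())),
        "#free\t" + ";".join(" ".join(map(str, row)) for row in world.free.tolist()),
    ]
    lines += [
        f"{m.room}\t{m.seq}\t{m.nascent if m.nascent is not None else '-'}"
        for m in world.molecules
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_snapshot(path, config: NSRWorldConfig) -> NSRWorld:
    """Inverse of :func:`save_snapshot`."""
    world = init_world(config)
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                tag, _, payload = line.partition("\t")
                if tag == "#ledger":
                    world.material_ledger = int(payload)
                elif tag == "#step":
                    world.step_count = int(payload)
                elif tag == "#precursors":
                    world.precursors = np.array(payload.split(), dtype=np.int64)
                elif tag == "#free":
                    world.free = np.array(
                        [r.split() for r in payload.split(";")], dtype=np.int64
                    )
                continue
            room, seq, nascent = line.split("\t")
            world.add_molecule(int(room), seq, None if nascent == "-" else nascent)
    return world
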