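"""miRanda-style duplex engine: local alignment score S and duplex MFE.

A mature miRNA is aligned antiparallel (3'→5') against a target window
(5'→3') with a Smith–Waterman/Gotoh dynamic program over *complementarity*:
Watson–Crick pairs score as matches, G:U wobbles as weak matches, and
columns pairing a miRNA seed position (2–8 from the mature 5' end) are
up-weighted by ``seed_scale``. The best local alignment's score is the
complementarity score S.

The duplex minimum free energy (MFE, kcal/mol) of an alignment is computed
from a packaged nearest-neighbor stack table plus constant internal
loop/bulge and helix-terminal penalties. This is a deliberately simplified
additive model — not a partition-function fold — sufficient because the
downstream analysis consumes per-allele MFE *differences*.

A hit is reported when S >= s_min and MFE <= mfe_max (defaults 80 and
−16 kcal/mol, both boundaries inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .seed_scan import MatureMiRNA, normalize_rna

logger = logging.getLogger(__name__)

WC_PAIRS = frozenset({"AU", "UA", "GC", "CG"})
WOBBLE_PAIRS = frozenset({"GU", "UG"})

#: masking character used when rescanning around accepted hits; never pairs
MASK = "N"


def pair_class(mirna_base: str, target_base: str) -> str:
    """Classify a paired column: 'WC', 'wobble' or 'mismatch'."""
    duo = mirna_base + target_base
    if duo in WC_PAIRS:
        return "WC"
    if duo in WOBBLE_PAIRS:
        return "wobble"
    return "mismatch"


@dataclass
class AlignmentParams:
    """Scoring constants for the complementarity alignment.

    Only the two reporting cutoffs (``s_min``, ``mfe_max``) are anchored in
    the published analysis; the remaining constants are explicit
    configuration in the spirit of miRanda's strong 5'-seed weighting.
    """

    match_score: float = 5.0
    wobble_score: float = 1.0
    mismatch_score: float = -3.0
    gap_open: float = -9.0      # cost of the first gap base
    gap_extend: float = -4.0    # cost of each additional gap base
    seed_scale: float = 4.0     # multiplier on columns pairing miRNA nt 2–8
    seed_span: tuple[int, int] = (2, 8)  # 1-based inclusive miRNA positions
    s_min: float = 80.0
    mfe_max: float = -16.0

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")
        if self.s_min <= 0:
            raise ValueError("s_min must be positive")
        if self.seed_scale < 1:
            raise ValueError("seed_scale must be >= 1")


@dataclass(frozen=True)
class AlignmentColumn:
    """One alignment column: miRNA base (or None), target base (or None)."""

    mirna_base: str | None
    target_base: str | None
    pair: str  # WC | wobble | mismatch | gap
    mirna_pos: int | None  # 1-based position from the mature 5' end


@dataclass
class DuplexAlignment:
    """A local miRNA::target alignment; empty columns mean "no hit"."""

    mirna_span: tuple[int, int]   # 0-based half-open, mature 5'→3' coords
    target_span: tuple[int, int]  # 0-based half-open on the target
    columns: list[AlignmentColumn]
    score_s: float

    @property
    def is_hit(self) -> bool:
        return bool(self.columns)

    def pretty(self) -> str:
        """Three-row text rendering (target 5'→3' on top)."""
        top, mid, bot = [], [], []
        for c in self.columns:
            t = c.target_base or "-"
            m = c.mirna_base or "-"
            top.append(t)
            bot.append(m)
            mid.append({"WC": "|", "wobble": ":", "mismatch": ".", "gap": " "}[c.pair])
        return "\n".join(
            [
                f"5' {''.join(top)} 3' target",
                f"   {''.join(mid)}",
                f"3' {''.join(bot)} 5' miRNA",
            ]
        )


def _substitution(params: AlignmentParams, cls: str, mirna_pos: int) -> float:
    base = {
        "WC": params.match_score,
        "wobble": params.wobble_score,
        "mismatch": params.mismatch_score,
    }[cls]
    lo, hi = params.seed_span
    if lo <= mirna_pos <= hi:
        base *= params.seed_scale
    return base


def local_align(
    mirna: MatureMiRNA | str,
    target: str,
    params: AlignmentParams | None = None,
) -> DuplexAlignment:
    """Best local complementarity alignment of ``mirna`` against ``target``.

    The miRNA is laid 3'→5' against the target 5'→3' (antiparallel duplex).
    Returns a zero-score alignment with no columns when no positive-scoring
    cell exists. Ties are broken by smallest target start, then shortest
    alignment. ``mirna`` may be a raw RNA string; position numbering for
    the seed up-weighting always counts from the mature 5' end.
    """
    params = params or AlignmentParams()
    t = normalize_rna(target, extra=MASK)
    if not t:
        raise ValueError("empty target sequence")
    mseq = mirna.sequence if isinstance(mirna, MatureMiRNA) else normalize_rna(mirna)
    if not mseq:
        raise ValueError("empty miRNA sequence")
    L = len(mseq)
    mrev = mseq[::-1]  # row i-1 pairs miRNA 1-based position L - i + 1
    n = len(t)

    NEG = float("-inf")
    # H: best local score ending at (i, j); E: gap in miRNA (consumes target);
    # F: gap in target (consumes miRNA).
    H = [[0.0] * (n + 1) for _ in range(L + 1)]
    E = [[NEG] * (n + 1) for _ in range(L + 1)]
    F = [[NEG] * (n + 1) for _ in range(L + 1)]
    go, ge = params.gap_open, params.gap_extend

    sub = [[0.0] * (n + 1) for _ in range(L + 1)]
    for i in range(1, L + 1):
        pos = L - i + 1
        mb = mrev[i - 1]
        row = sub[i]
        for j in range(1, n + 1):
            tb = t[j - 1]
            if tb == MASK or mb == MASK:
                cls = "mismatch"
            else:
                cls = pair_class(mb, tb)
            row[j] = _substitution(params, cls, pos)

    best = 0.0
    best_cells: list[tuple[int, int]] = []
    for i in range(1, L + 1):
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Fi, Fi1 = E[i], F[i], F[i - 1]
        si = sub[i]
        for j in range(1, n + 1):
            e = max(Hi[j - 1] + go, Ei[j - 1] + ge)
            f = max(Hi1[j] + go, Fi1[j] + ge)
            h = Hi1[j - 1] + si[j]
            v = max(0.0, h, e, f)
            Ei[j] = e
            Fi[j] = f
            Hi[j] = v
            if v > best:
                best = v
                best_cells = [(i, j)]
            elif v == best and v > 0:
                best_cells.append((i, j))

    if best <= 0:
        return DuplexAlignment((0, 0), (0, 0), [], 0.0)

    candidates = []
    for (i, j) in best_cells:
        aln = _traceback(i, j, H, E, F, sub, mrev, t, L, go, ge)
        candidates.append(aln)
    candidates.sort(key=lambda a: (a.target_span[0], len(a.columns), a.mirna_span[0]))
    chosen = candidates[0]
    chosen.score_s = best
    return chosen


def _traceback(i, j, H, E, F, sub, mrev, t, L, go, ge) -> DuplexAlignment:
    cols: list[AlignmentColumn] = []
    state = "H"
    end_i, end_j = i, j
    while i > 0 and j > 0:
        if state == "H":
            v = H[i][j]
            if v == 0:
                break
            if v == H[i - 1][j - 1] + sub[i][j]:
                mb, tb = mrev[i - 1], t[j - 1]
                pos = L - i + 1
                cls = "mismatch" if MASK in (mb, tb) else pair_class(mb, tb)
                cols.append(AlignmentColumn(mb, tb, cls, pos))
                i -= 1
                j -= 1
            elif v == E[i][j]:
                state = "E"
            elif v == F[i][j]:
                state = "F"
            else:  # pragma: no cover - defensive
                break
        elif state == "E":
            v = E[i][j]
            cols.append(AlignmentColumn(None, t[j - 1], "gap", None))
            if v == H[i][j - 1] + go:
                state = "H"
            j -= 1
        else:  # state == "F"
            v = F[i][j]
            pos = L - i + 1
            cols.append(AlignmentColumn(mrev[i - 1], None, "gap", pos))
            if v == H[i - 1][j] + go:
                state = "H"
            i -= 1
    cols.reverse()
    # DP rows count the miRNA 3'→5'; convert to mature 5'→3' coordinates.
    mirna_span = (L - end_i, L - i)
    target_span = (j, end_j)
    return DuplexAlignment(mirna_span, target_span, cols, 0.0)


# --------------------------------------------------------------------------
# Duplex free energy


def _wc_stack_table() -> dict[tuple[str, str], float]:
    """Nearest-neighbor stack ΔG°37 (kcal/mol).

    Keys are (target dinucleotide 5'→3', miRNA dinucleotide 3'→5' written
    left-to-right under it). Watson–Crick entries are the standard Turner
    constants; G:U-containing entries are an approximate packaged set. The
    closure adds the antiparallel-symmetric duplicate of every entry.
    """
    seed = {
        # Watson–Crick / Watson–Crick
        ("AA", "UU"): -0.93,
        ("AU", "UA"): -1.10,
        ("UA", "AU"): -1.33,
        ("CU", "GA"): -2.08,
        ("CA", "GU"): -2.11,
        ("GU", "CA"): -2.24,
        ("GA", "CU"): -2.35,
        ("CG", "GC"): -2.36,
        ("GG", "CC"): -3.26,
        ("GC", "CG"): -3.42,
        # one G:U wobble (approximate)
        ("AG", "UU"): -0.55,
        ("AU", "UG"): -1.36,
        ("CG", "GU"): -1.41,
        ("CU", "GG"): -1.77,
        ("GG", "CU"): -1.53,
        ("GU", "CG"): -2.51,
        ("UG", "AU"): -1.00,
        ("UU", "AG"): -0.76,
        # two G:U wobbles (approximate)
        ("GG", "UU"): -0.50,
        ("GU", "UG"): -0.40,
        ("UG", "GU"): 1.29,
    }
    table: dict[tuple[str, str], float] = {}
    for (top, bot), dg in seed.items():
        table[(top, bot)] = dg
        table[(bot[::-1], top[::-1])] = dg  # antiparallel symmetry
    return table


@dataclass
class EnergyModel:
    """Simplified nearest-neighbor duplex energy model."""

    stack_energy: dict[tuple[str, str], float] = field(default_factory=_wc_stack_table)
    loop_penalty: float = 4.0      # kcal/mol per internal loop / bulge event
    terminal_penalty: float = 0.5  # kcal/mol per helix end

    def __post_init__(self) -> None:
        self._warned_missing = False


def default_energy_model() -> EnergyModel:
    return EnergyModel()


def duplex_energy(alignment: DuplexAlignment, model: EnergyModel | None = None) -> float:
    """Free energy (kcal/mol) of an aligned duplex.

    Sum of stack energies over adjacent paired columns, plus one loop
    penalty per maximal run of unpaired (gap/mismatch) columns, plus a
    terminal penalty at each helix end. An alignment with no paired
    columns has energy 0 (no stable duplex).
    """
    model = model or default_energy_model()
    cols = alignment.columns
    paired = [c.pair in ("WC", "wobble") for c in cols]
    if not any(paired):
        return 0.0
    energy = 0.0
    helix_runs = 0
    loop_runs = 0
    prev = None  # None outside any run, else bool paired-state of current run
    for flag in paired:
        if flag != prev:
            if flag:
                helix_runs += 1
            else:
                loop_runs += 1
            prev = flag
    for k in range(len(cols) - 1):
        if paired[k] and paired[k + 1]:
            key = (
                cols[k].target_base + cols[k + 1].target_base,
                cols[k].mirna_base + cols[k + 1].mirna_base,
            )
            dg = model.stack_energy.get(key)
            if dg is None:
                if not model._warned_missing:
                    logger.warning("stack %r absent from energy table; treated as loop", key)
                    model._warned_missing = True
                dg = model.loop_penalty
            energy += dg
    energy += model.loop_penalty * loop_runs
    energy += model.terminal_penalty * 2 * helix_runs
    return energy


@dataclass
class DuplexHit:
    """One accepted alignment hit with its score S and MFE."""

    mirna_id: str
    target_id: str
    alignment: DuplexAlignment
    score_s: float
    mfe: float

    @property
    def target_span(self) -> tuple[int, int]:
        return self.alignment.target_span


def scan_hits(
    mirna: MatureMiRNA,
    target_id: str,
    target: str,
    params: AlignmentParams | None = None,
    model: EnergyModel | None = None,
    max_hits: int = 10,
) -> list[DuplexHit]:
    """All non-overlapping hits with S >= s_min and MFE <= mfe_max.

    The target span of each accepted hit is masked and the remainder
    rescanned, so multiple independent sites on one target are reported.
    """
    params = params or AlignmentParams()
    model = model or default_energy_model()
    work = list(normalize_rna(target, extra=MASK))
    hits: list[DuplexHit] = []
    for _ in range(max_hits):
        aln = local_align(mirna, "".join(work), params)
        if not aln.is_hit:
            break
        mfe = duplex_energy(aln, model)
        if aln.score_s >= params.s_min and mfe <= params.mfe_max:
            hits.append(DuplexHit(mirna.mirna_id, target_id, aln, aln.score_s, mfe))
            for k in range(*aln.target_span):
                work[k] = MASK
        else:
            break
    return hits


def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Length of overlap between two half-open intervals (0 when disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def max_abs_mfe_diff(
    hits_ref: Sequence[DuplexHit],
    hits_alt: Sequence[DuplexHit],
) -> float:
    """Maximum |MFE_ref − MFE_alt| over matched hits of one SNP::miRNA pair.

    Hits are matched across alleles by overlapping target span (the two
    allele sequences share coordinates); a hit with no counterpart is
    compared against 0 kcal/mol (no stable duplex on the other allele).
    Returns 0 when both lists are empty.
    """
    remaining = list(hits_alt)
    diffs: list[float] = []
    for r in hits_ref:
        overlapping = [a for a in remaining if _spans_overlap(r.target_span, a.target_span)]
        if overlapping:
            a = max(overlapping, key=lambda h: _spans_overlap(r.target_span, h.target_span))
            remaining.remove(a)
            diffs.append(abs(r.mfe - a.mfe))
        else:
            diffs.append(abs(r.mfe))
    diffs.extend(abs(a.mfe) for a in remaining)
    return max(diffs, default=0.0)
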