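"""Control-region annotation: domains, conserved boxes, C-strings, repeats.

The avian control region splits into three domains: the extended
termination-associated sequence (ETAS) domain I, the central conserved
domain II carrying the F/E/D/C/bird-similarity/B boxes, and the conserved
sequence block (CSB) domain III.  Conserved boxes are short motifs matched
here by Hamming distance over fixed-length windows (no indels); a
poly-cytosine "C-string" near the start of domain I may be interrupted by
single non-C bases.

Tandem repeats (typical of the degenerate remnant CR2) are found with a
k-mer-seeded period scan: recurrence distances of exact 8-mers propose
candidate periods, each seed is extended while the sequence agrees with
itself at that lag within an identity threshold, and the surviving regions
are reported with period, fractional copy number (region length / period)
and a columnwise majority-vote consensus.  This is deliberately simpler
than wraparound dynamic programming: it targets the near-exact, short-period
repeats seen in mitochondrial control regions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources

import yaml

__all__ = [
    "CRDomainSpec",
    "MotifDef",
    "MotifHit",
    "TandemRepeat",
    "DEFAULT_DOMAIN_SPEC",
    "load_motif_library",
    "partition_domains",
    "scan_motifs",
    "find_cstring",
    "find_tandem_repeats",
]


@dataclass(frozen=True)
class CRDomainSpec:
    """Domain I/II/III boundaries in CR-local 1-based coordinates."""

    domain1: tuple[int, int]
    domain2: tuple[int, int]
    domain3: tuple[int, int]

    def __post_init__(self) -> None:
        d1, d2, d3 = self.domain1, self.domain2, self.domain3
        for lo, hi in (d1, d2, d3):
            if lo > hi:
                raise ValueError("domain start after end")
        if not (d1[1] + 1 == d2[0] and d2[1] + 1 == d3[0]):
            raise ValueError("domains must be contiguous and ordered I < II < III")

    def domain_of(self, pos: int) -> str | None:
        for label, (lo, hi) in zip(
            ("I", "II", "III"), (self.domain1, self.domain2, self.domain3)
        ):
            if lo <= pos <= hi:
                return label
        return None


#: Boundaries reported for the P. fuscatus CR1 (1,104 nt).
DEFAULT_DOMAIN_SPEC = CRDomainSpec((1, 424), (425, 859), (860, 1104))


@dataclass(frozen=True)
class MotifDef:
    box_name: str
    pattern: str
    max_mismatch: int = 3
    expected_domain: str | None = None
    provenance: str = "study"

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        if self.max_mismatch >= len(self.pattern):
            raise ValueError("max_mismatch must be < pattern length")


@dataclass(frozen=True)
class MotifHit:
    box_name: str
    start: int  # CR-local, 1-based
    mismatches: int
    matched_seq: str
    domain: str | None = None


@dataclass(frozen=True)
class TandemRepeat:
    start: int  # CR-local, 1-based inclusive
    end: int
    period: int
    copy_number: float  # full precision; round to 1 decimal in reports
    consensus: str
    pct_identity: float
    score: int

    @property
    def copy_number_1dp(self) -> float:
        return round(self.copy_number, 1)


def load_motif_library() -> list[MotifDef]:
    """The packaged conserved-box library (study boxes plus literature-
    consensus boxes used only so their absence is reportable)."""
    text = resources.files("mitochar.data").joinpath("motifs.yaml").read_text()
    data = yaml.safe_load(text)
    return [
        MotifDef(
            box_name=b["name"],
            pattern=b["pattern"].upper(),
            max_mismatch=int(b.get("max_mismatch", 3)),
            expected_domain=b.get("expected_domain"),
            provenance=b.get("provenance", "study"),
        )
        for b in data["boxes"]
    ]


def partition_domains(
    cr_seq: str, spec: CRDomainSpec = DEFAULT_DOMAIN_SPEC
) -> dict[str, str]:
    """Split a CR sequence into its three domains.

    The concatenation of the returned parts reproduces
    ``cr_seq[spec.domain1[0]-1 : spec.domain3[1]]``.
    """
    if spec.domain3[1] > len(cr_seq):
        raise IndexError(
            f"domain boundary {spec.domain3[1]} beyond sequence of {len(cr_seq)} nt"
        )
    return {
        "I": cr_seq[spec.domain1[0] - 1 : spec.domain1[1]],
        "II": cr_seq[spec.domain2[0] - 1 : spec.domain2[1]],
        "III": cr_seq[spec.domain3[0] - 1 : spec.domain3[1]],
    }


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def scan_motifs(
    cr_seq: str,
    library: list[MotifDef],
    domain_spec: CRDomainSpec | None = None,
) -> list[MotifHit]:
    """Best (minimum-Hamming, leftmost) window per box within its mismatch cap.

    Boxes with no window within ``max_mismatch`` are simply absent from the
    result - mirroring how boxes not found in a control region are reported.
    """
    if not library:
        raise ValueError("empty motif library")
    seq = cr_seq.upper()
    hits: list[MotifHit] = []
    for motif in library:
        m = len(motif.pattern)
        best_d, best_i = motif.max_mismatch + 1, None
        for i in range(len(seq) - m + 1):
            d = _hamming(seq[i : i + m], motif.pattern)
            if d < best_d:
                best_d, best_i = d, i
                if d == 0:
                    break
        if best_i is None:
            continue
        start = best_i + 1
        hits.append(
            MotifHit(
                box_name=motif.box_name,
                start=start,
                mismatches=best_d,
                matched_seq=seq[best_i : best_i + m],
                domain=domain_spec.domain_of(start) if domain_spec else None,
            )
        )
    return hits


def find_cstring(
    cr_seq: str, min_len: int = 10, max_interruptions: int = 1
) -> list[tuple[int, int, int]]:
    """Maximal C-runs allowing up to ``max_interruptions`` single non-C bases.

    Every interruption must be a single base flanked by at least one C on each
    side; overlapping candidate windows are merged to maximal, and windows are
    reported as ``(start, end, length)`` (1-based inclusive), longest first
    with leftmost tie-break, after discarding windows shorter than
    ``min_len``.  Non-overlapping results only.
    """
    if min_len < 5:
        raise ValueError("min_len must be >= 5")
    seq = cr_seq.upper()
    n = len(seq)
    # maximal pure C runs as (start0, end0) half-open
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if seq[i] == "C":
            j = i
            while j < n and seq[j] == "C":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    # candidate windows: any k+1 consecutive runs joined by single-base gaps,
    # k <= max_interruptions
    candidates: list[tuple[int, int]] = []
    for a in range(len(runs)):
        end = runs[a][1]
        start = runs[a][0]
        candidates.append((start, end))
        used = 0
        b = a
        while b + 1 < len(runs) and used < max_interruptions:
            gap = runs[b + 1][0] - runs[b][1]
            if gap != 1:
                break
            used += 1
            b += 1
            candidates.append((start, runs[b][1]))
        # keep only the maximal window for this start: drop shorter prefixes
    # filter, deduplicate, sort by length desc then position
    windows = sorted(
        {(s, e) for s, e in candidates if e - s >= min_len},
        key=lambda w: (-(w[1] - w[0]), w[0]),
    )
    chosen: list[tuple[int, int]] = []
    for s, e in windows:
        if all(e <= cs or s >= ce for cs, ce in chosen):
            chosen.append((s, e))
    chosen.sort()
    return [(s + 1, e, e - s) for s, e in chosen]


# ---------------------------------------------------------------------------
# tandem repeats


def _candidate_periods(
    seq: str, min_period: int, max_period: int, k: int = 8
) -> list[tuple[int, int]]:
    """(position, period) seeds from exact k-mer recurrences."""
    positions: dict[str, list[int]] = {}
    seeds: set[tuple[int, int]] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        for j in positions.get(kmer, ()):
            d = i - j
            if min_period <= d <= max_period:
                seeds.add((j, d))
        positions.setdefault(kmer, []).append(i)
    return sorted(seeds)


_MISMATCH_PENALTY = 2
_XDROP = 6


def _extend_region(seq: str, pos: int, period: int) -> tuple[int, int, int]:
    """X-drop extension of a lag-``period`` self-match around ``pos``.

    Positions i with ``seq[i] == seq[i+period]`` score +1, mismatches -2;
    extension in each direction stops once the running score falls
    ``_XDROP`` below its best, and the boundary is the best-scoring
    position.  Returns ``(region_start0, region_end0_exclusive, matches)``
    where the region covers ``[start, last_aligned + period]``.
    """
    n = len(seq)

    def run(start: int, step: int) -> int:
        best, cur = 0, 0
        best_i = start - step
        i = start
        while 0 <= i <= n - period - 1:
            cur += 1 if seq[i] == seq[i + period] else -_MISMATCH_PENALTY
            if cur > best:
                best, best_i = cur, i
            if cur < best - _XDROP:
                break
            i += step
        return best_i

    right = run(pos, +1)
    left = run(pos, -1)
    if right < left:
        return pos, pos, 0
    matches = sum(
        1 for i in range(left, right + 1) if seq[i] == seq[i + period]
    )
    return left, right + period + 1, matches


def _consensus(units: list[str], period: int) -> str:
    """Columnwise majority over stacked repeat units (ties -> first unit)."""
    out = []
    for col in range(period):
        column = [u[col] for u in units if col < len(u)]
        counts = Counter(column)
        top = max(counts.values())
        winners = {b for b, c in counts.items() if c == top}
        out.append(column[0] if column[0] in winners else sorted(winners)[0])
    return "".join(out)


def find_tandem_repeats(
    seq: str,
    min_period: int = 10,
    max_period: int = 200,
    min_copies: float = 1.8,
    min_identity: float = 80.0,
) -> list[TandemRepeat]:
    """Detect tandem repeats by k-mer-seeded period scanning.

    Candidate periods come from recurrence distances of exact 8-mers; each
    seed is extended while the region matches itself at that lag within
    ``min_identity``; regions shorter than ``min_copies`` periods are
    dropped.  Surviving regions are reported highest score first (score =
    aligned matching positions) and overlapping lower-scoring regions are
    suppressed.  ``copy_number`` is region length / period (full precision;
    reports round to 1 decimal); the consensus is the columnwise majority of
    the stacked units.
    """
    if not 2 <= min_period <= max_period:
        raise ValueError("need 2 <= min_period <= max_period")
    seq = seq.upper()
    if max_period > len(seq) / min_copies:
        max_period = int(len(seq) / min_copies)
    found: dict[tuple[int, int], TandemRepeat] = {}
    for pos, period in _candidate_periods(seq, min_period, max_period):
        start, end, matches = _extend_region(seq, pos, period)
        length = end - start
        if length < min_copies * period:
            continue
        aligned = length - period
        identity = 100.0 * matches / aligned if aligned else 0.0
        if identity < min_identity:
            continue
        units = [seq[i : i + period] for i in range(start, end, period)]
        key = (start, period)
        cand = TandemRepeat(
            start=start + 1,
            end=end,
            period=period,
            copy_number=length / period,
            consensus=_consensus(units, period),
            pct_identity=identity,
            score=matches,
        )
        prev = found.get(key)
        if prev is None or cand.score > prev.score:
            found[key] = cand
    ranked = sorted(
        found.values(), key=lambda r: (-r.score, r.period, r.start)
    )
    chosen: list[TandemRepeat] = []
    for r in ranked:
        if all(r.end < c.start or r.start > c.end for c in chosen):
            chosen.append(r)
    return chosen
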