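"""Catalogue of miRNA subsequence motifs and target-site scanning.

A mature miRNA of length L defines, for every window length k in a configured
range (default 6-9 nt), all L-k+1 positional subsequences.  Each subsequence's
reverse complement is a candidate binding site that can be searched for in
mRNA region sequences (5'UTR / CDS / 3'UTR).  Windows are classified by where
they originate on the miRNA: ``seed`` windows fully cover the canonical seed
(nucleotides 2-7, 1-based), ``threeprime`` windows lie entirely within the
3' half of the molecule, and everything else is ``central``.

Scanning counts overlapping exact matches of each target site per transcript
region, stratified by differential-expression group.  For speed the scanner
pre-aggregates dense k-mer occurrence/presence tables per (region, group), so
that re-scanning the thousands of catalogues arising from shuffled-miRNA null
replicates costs only array lookups.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

REGIONS = ("UTR5", "CDS", "UTR3")
GROUPS = ("up", "down", "unchanged")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# base -> 2-bit code; -1 marks characters outside the DNA alphabet
_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


class AlphabetError(ValueError):
    """Sequence contains characters outside {A, C, G, T, U}."""


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and convert RNA U to DNA T.

    Raises :class:`AlphabetError` for anything outside {A, C, G, T, U}.
    """
    s = seq.strip().upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise AlphabetError(f"invalid nucleotide characters: {sorted(bad)!r}")
    return s


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement, returned in the DNA alphabet."""
    return normalize_sequence(seq)[::-1].translate(_COMPLEMENT)


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence, stored 5'->3' in the DNA alphabet."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if len(self.sequence) < 9:
            raise ValueError(
                f"mature miRNA {self.name!r} is {len(self.sequence)} nt; need >= 9"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


#: hsa-miR-10b-5p, the reverse complement of the antisense inhibitor
#: 5'-CACAAATTCGGTTCTACAGGGTA-3' used to derepress its targets.
MIR10B = MatureMiRNA("hsa-miR-10b-5p", "UACCCUGUAGAACCGAAUUUGUG")


def classify_origin(
    start: int,
    k: int,
    mirna_length: int,
    seed_span: tuple[int, int] = (2, 7),
    three_prime_start: int | None = None,
) -> str:
    """Positional origin class of a miRNA window.

    Parameters use 0-based ``start``; ``seed_span`` is the 1-based inclusive
    span of the seed (default nucleotides 2-7).  A window is ``seed`` when it
    fully covers the seed span, ``threeprime`` when it lies entirely at
    1-based positions > ceil(L/2) (i.e. within the 3' half), else ``central``.
    """
    first = start + 1  # 1-based
    last = start + k
    if three_prime_start is None:
        three_prime_start = math.ceil(mirna_length / 2) + 1
    if first <= seed_span[0] and last >= seed_span[1]:
        return "seed"
    if first >= three_prime_start:
        return "threeprime"
    return "central"


@dataclass(frozen=True)
class MotifSpec:
    """One positional k-mer window of a mature miRNA.

    ``subsequence`` is the miRNA window 5'->3'; ``target_site`` is its DNA
    reverse complement, the string actually searched for in mRNA regions.
    """

    subsequence: str
    k: int
    start: int  # 0-based offset within the miRNA
    origin_class: str
    target_site: str

    @property
    def start_1based(self) -> int:
        return self.start + 1


def enumerate_motifs(
    mirna: MatureMiRNA | str,
    k_min: int = 6,
    k_max: int = 9,
    seed_span: tuple[int, int] = (2, 7),
    three_prime_start: int | None = None,
) -> list[MotifSpec]:
    """All positional subsequence windows of ``mirna`` with k in [k_min, k_max].

    Returns sum_{k}(L - k + 1) windows ordered by (k, start), window lengths
    exceeding the sequence contributing none.  Duplicate subsequences
    occurring at different positions are retained as distinct entries; use
    :func:`collapse_motifs` for the deduplicated counting view.  A plain
    nucleotide string is accepted in place of a :class:`MatureMiRNA`.
    """
    seq = mirna.sequence if isinstance(mirna, MatureMiRNA) else normalize_sequence(mirna)
    length = len(seq)
    if not (1 <= k_min <= k_max):
        raise ValueError(f"need 1 <= k_min <= k_max; got k_min={k_min}, k_max={k_max}")
    if k_min > length:
        raise ValueError(
            f"k_min={k_min} exceeds the {length}-nt sequence; no windows exist"
        )
    out = []
    for k in range(k_min, min(k_max, length) + 1):
        for start in range(length - k + 1):
            sub = seq[start : start + k]
            out.append(
                MotifSpec(
                    subsequence=sub,
                    k=k,
                    start=start,
                    origin_class=classify_origin(
                        start, k, length, seed_span, three_prime_start
                    ),
                    target_site=reverse_complement(sub),
                )
            )
    return out


@dataclass(frozen=True)
class CollapsedMotif:
    """A deduplicated motif: one subsequence, possibly several positions.

    A site match in an mRNA cannot distinguish identical subsequences drawn
    from different miRNA positions, so counting collapses them; the positional
    annotations (and the union of their origin classes) are retained.
    """

    subsequence: str
    k: int
    target_site: str
    starts: tuple[int, ...]
    origin_classes: tuple[str, ...]  # sorted union over positions

    @property
    def origin_label(self) -> str:
        return ",".join(self.origin_classes)


def collapse_motifs(motifs: Sequence[MotifSpec]) -> list[CollapsedMotif]:
    """Merge positional duplicates; ordered by (k, first start)."""
    by_sub: dict[str, list[MotifSpec]] = defaultdict(list)
    for m in motifs:
        by_sub[m.subsequence].append(m)
    out = []
    for sub, specs in by_sub.items():
        out.append(
            CollapsedMotif(
                subsequence=sub,
                k=specs[0].k,
                target_site=specs[0].target_site,
                starts=tuple(s.start for s in specs),
                origin_classes=tuple(sorted({s.origin_class for s in specs})),
            )
        )
    out.sort(key=lambda c: (c.k, c.starts[0]))
    return out


def shuffle_sequence(seq: str, rng: np.random.Generator) -> str:
    """Uniform random permutation of a nucleotide string (composition preserved)."""
    return "".join(rng.permutation(np.array(list(normalize_sequence(seq)))))


def shuffle_mirna(mirna: MatureMiRNA, rng: np.random.Generator) -> MatureMiRNA:
    """Shuffled copy of a mature miRNA; same seed gives the same permutation."""
    return MatureMiRNA(f"{mirna.name}|shuffled", shuffle_sequence(mirna.sequence, rng))


def count_occurrences(region_sequence: str, target_site: str) -> int:
    """Number of exact matches of ``target_site``, overlapping occurrences counted."""
    if not target_site:
        raise ValueError("target_site must be non-empty")
    if not region_sequence:
        return 0
    n = 0
    pos = region_sequence.find(target_site)
    while pos != -1:
        n += 1
        pos = region_sequence.find(target_site, pos + 1)
    return n


# ---------------------------------------------------------------------------
# dense k-mer tables: aggregate occurrence/presence counts per (region, group)
# ---------------------------------------------------------------------------


def encode_kmers(seq: str, k: int) -> np.ndarray:
    """2-bit codes of every k-mer of ``seq``; windows with non-ACGT bases dropped."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        window = arr[j : j + n]
        codes = codes * 4 + window
        valid &= window >= 0
    return codes[valid]


def encode_site(site: str) -> tuple[int, int]:
    """(k, integer code) of a single site; raises AlphabetError on bad bases."""
    site = normalize_sequence(site)
    code = 0
    for c in site:
        code = code * 4 + int(_ENCODE[ord(c)])
    return len(site), code


class KmerTable:
    """Dense occurrence and presence counts for all k-mers, k in ``ks``.

    ``occ[k][code]`` is the total number of (overlapping) occurrences summed
    over the sequences added; ``presence[k][code]`` is the number of sequences
    containing the k-mer at least once.
    """

    def __init__(self, ks: Sequence[int] = (6, 7, 8, 9)) -> None:
        self.ks = tuple(ks)
        self.occ = {k: np.zeros(4**k, dtype=np.int64) for k in self.ks}
        self.presence = {k: np.zeros(4**k, dtype=np.int64) for k in self.ks}
        self.n_sequences = 0
        self.total_length = 0

    def add_sequence(self, seq: str) -> None:
        self.n_sequences += 1
        self.total_length += len(seq)
        for k in self.ks:
            codes = encode_kmers(seq, k)
            if codes.size:
                np.add.at(self.occ[k], codes, 1)
                self.presence[k][np.unique(codes)] += 1

    def lookup(self, site: str) -> tuple[int, int]:
        """(occurrences, sequences_with_site) for one target site."""
        k, code = encode_site(site)
        if k not in self.occ:
            raise KeyError(f"site length {k} outside table range {self.ks}")
        return int(self.occ[k][code]), int(self.presence[k][code])


@dataclass
class RegionGroupTables:
    """Pre-aggregated k-mer tables keyed by (region, group), plus group sizes.

    ``region_group_sizes`` counts transcripts of each group that actually have
    the region (transcripts lacking a region are excluded from that region's
    denominator); ``group_sizes`` counts all grouped transcripts.
    """

    tables: dict[tuple[str, str], KmerTable]
    group_sizes: dict[str, int]
    region_group_sizes: dict[tuple[str, str], int]
    ks: tuple[int, ...]
    n_missing: int = 0  # grouped transcripts absent from the annotation


@dataclass
class MotifCounts:
    """Occurrence statistics for a motif catalogue against grouped regions.

    ``occurrences[(motif, region, group)]`` sums overlapping matches over all
    transcripts of the group; ``transcripts_with_site`` counts each transcript
    at most once (presence/absence mode).
    """

    motifs: list[CollapsedMotif]
    occurrences: dict[tuple[str, str, str], int]
    transcripts_with_site: dict[tuple[str, str, str], int]
    group_sizes: dict[str, int]
    region_group_sizes: dict[tuple[str, str], int]

    def to_frame(self):
        import pandas as pd

        rows = []
        for m in self.motifs:
            for region in REGIONS:
                for group in GROUPS:
                    key = (m.subsequence, region, group)
                    rows.append(
                        {
                            "motif": m.subsequence,
                            "k": m.k,
                            "origin_class": m.origin_label,
                            "target_site": m.target_site,
                            "region": region,
                            "group": group,
                            "occurrences": self.occurrences.get(key, 0),
                            "transcripts_with_site": self.transcripts_with_site.get(
                                key, 0
                            ),
                            "group_size": self.region_group_sizes.get(
                                (region, group), 0
                            ),
                        }
                    )
        return pd.DataFrame(rows)


def build_tables(
    annotation: Mapping[tuple[str, str], str],
    groups: Mapping[str, Iterable[str]] | "object",
    ks: Sequence[int] = (6, 7, 8, 9),
) -> RegionGroupTables:
    """Aggregate k-mer tables per (region, DE group) over an annotation.

    ``annotation`` maps (transcript_id, region) -> sequence; ``groups`` either
    maps group name -> transcript ids or is a TranscriptGroups-like object
    with ``up``/``down``/``unchanged`` attributes.  Grouped transcripts with
    no sequence in any region are excluded with a count kept in
    ``n_missing`` (the caller is expected to log it).
    """
    if hasattr(groups, "up"):
        group_map = {g: getattr(groups, g) for g in GROUPS}
    else:
        group_map = {g: groups.get(g, ()) for g in GROUPS}

    tables = {(r, g): KmerTable(ks) for r in REGIONS for g in GROUPS}
    region_group_sizes = {(r, g): 0 for r in REGIONS for g in GROUPS}
    group_sizes = {}
    n_missing = 0
    for group, tids in group_map.items():
        tids = sorted(tids)
        group_sizes[group] = len(tids)
        for tid in tids:
            seen = False
            for region in REGIONS:
                seq = annotation.get((tid, region))
                if seq is None:
                    continue
                seen = True
                tables[(region, group)].add_sequence(seq)
                region_group_sizes[(region, group)] += 1
            if not seen:
                n_missing += 1
    return RegionGroupTables(
        tables=tables,
        group_sizes=group_sizes,
        region_group_sizes=region_group_sizes,
        ks=tuple(ks),
        n_missing=n_missing,
    )


def count_catalogue(
    tables: RegionGroupTables, motifs: Sequence[MotifSpec] | Sequence[CollapsedMotif]
) -> MotifCounts:
    """Count a motif catalogue against pre-built (region, group) tables."""
    if motifs and isinstance(motifs[0], MotifSpec):
        collapsed = collapse_motifs(motifs)  # type: ignore[arg-type]
    else:
        collapsed = list(motifs)  # type: ignore[assignment]
    occurrences: dict[tuple[str, str, str], int] = {}
    with_site: dict[tuple[str, str, str], int] = {}
    for m in collapsed:
        for (region, group), table in tables.tables.items():
            occ, pres = table.lookup(m.target_site)
            occurrences[(m.subsequence, region, group)] = occ
            with_site[(m.subsequence, region, group)] = pres
    return MotifCounts(
        motifs=collapsed,
        occurrences=occurrences,
        transcripts_with_site=with_site,
        group_sizes=dict(tables.group_sizes),
        region_group_sizes=dict(tables.region_group_sizes),
    )


def scan(
    annotation: Mapping[tuple[str, str], str],
    motifs: Sequence[MotifSpec],
    groups,
    ks: Sequence[int] | None = None,
) -> MotifCounts:
    """Count every (motif, region, group) triple over an annotation.

    Convenience wrapper over :func:`build_tables` + :func:`count_catalogue`;
    reuse the tables directly when re-scanning many catalogues (e.g. the
    shuffled-miRNA null).
    """
    if ks is None:
        ks = sorted({m.k for m in motifs})
    tables = build_tables(annotation, groups, ks=ks)
    return count_catalogue(tables, motifs)
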