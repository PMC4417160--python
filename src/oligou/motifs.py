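"""Strand-aware positional k-mer analysis around feature 3' ends.

Profiles motif occurrence (and full k-mer frequency rankings) in windows
anchored at the transcription termination site (TTS) of annotated features —
here, snRNA genes whose downstream regions carry the U-rich stretches that
recruit the nuclear exosome adaptor.  Coordinates are BED 0-based half-open
throughout; the 3' anchor is ``end`` on the + strand and ``start`` on the
- strand, and oriented position 0 is the first nucleotide downstream of the
3' end on the feature's own strand.

Motifs may be written in RNA (U) or DNA (T) alphabet; U maps to T.
Overlapping occurrences are counted at every start (a run of seven T contains
three TTTTT starts), because homopolymer runs are the object of interest.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Feature",
    "FeatureSet",
    "Window",
    "OrientedWindow",
    "PositionalProfile",
    "KmerRanking",
    "filter_nonoverlapping",
    "extract_windows",
    "positional_profile",
    "rank_kmers",
    "smooth_profile",
    "normalize_motif",
    "reverse_complement",
    "read_bed6",
    "write_bed6",
    "read_fasta",
    "write_fasta",
    "ensembl_tsv_to_features",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_motif(motif: str) -> str:
    """Uppercase and map U->T; reject characters outside A,C,G,T,U."""
    m = motif.upper().replace("U", "T")
    if not m or any(c not in "ACGT" for c in m):
        raise ValueError(f"motif must be over A,C,G,U/T: {motif!r}")
    return m


@dataclass(frozen=True)
class Feature:
    chrom: str
    start: int
    end: int
    strand: str
    name: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"feature {self.name}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.name}: strand must be + or -")

    @property
    def three_prime(self) -> int:
        """Genomic coordinate of the first base downstream of the 3' end."""
        return self.end if self.strand == "+" else self.start - 1


@dataclass
class FeatureSet:
    features: list[Feature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)


@dataclass(frozen=True)
class Window:
    """TTS-anchored window: oriented positions -upstream .. downstream-1."""

    upstream_nt: int = 200
    downstream_nt: int = 600

    def __post_init__(self) -> None:
        if self.upstream_nt < 0 or self.downstream_nt < 0:
            raise ValueError("window extents must be non-negative")
        if self.upstream_nt + self.downstream_nt == 0:
            raise ValueError("window must have positive total extent")


@dataclass
class OrientedWindow:
    """Oriented (5'->3' on the feature strand) window sequence.

    ``first_position`` is the oriented coordinate of ``seq[0]``; an unclipped
    window has ``first_position == -upstream`` and length up+down.
    """

    name: str
    seq: str
    first_position: int
    clipped: bool = False

    @property
    def positions(self) -> range:
        return range(self.first_position, self.first_position + len(self.seq))


def filter_nonoverlapping(features: FeatureSet) -> FeatureSet:
    """Drop every feature whose genomic span intersects any other feature
    (both members of an overlapping pair are removed; strand-agnostic)."""
    feats = features.features
    by_chrom: dict[str, list[int]] = {}
    for i, f in enumerate(feats):
        by_chrom.setdefault(f.chrom, []).append(i)
    bad: set[int] = set()
    for idxs in by_chrom.values():
        idxs = sorted(idxs, key=lambda i: feats[i].start)
        # start-sorted sweep: feature j overlaps i (j after i) iff
        # feats[j].start < feats[i].end
        for a, i in enumerate(idxs):
            for j in idxs[a + 1:]:
                if feats[j].start >= feats[i].end:
                    break
                bad.add(i)
                bad.add(j)
    return FeatureSet([f for i, f in enumerate(feats) if i not in bad])


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Plus-strand slice [start, end), clipped to the chromosome; works for a
    plain mapping of strings or a pyfaidx.Fasta."""
    if chrom not in genome:
        raise KeyError(chrom)
    ref = genome[chrom]
    n = len(ref)
    lo, hi = max(start, 0), min(end, n)
    if lo >= hi:
        return ""
    return str(ref[lo:hi]).upper()


def extract_windows(
    genome: Mapping[str, str],
    features: FeatureSet | Iterable[Feature],
    window: Window = Window(),
) -> list[OrientedWindow]:
    """Extract oriented TTS windows for every feature.

    + strand: plus-strand sequence of [end - upstream, end + downstream).
    - strand: reverse complement of [start - downstream, start + upstream).
    Windows are clipped at chromosome ends and the clipping recorded so that
    positional coverage can be computed downstream.
    """
    out = []
    for f in features:
        if f.chrom not in genome:
            raise KeyError(f"chromosome {f.chrom!r} (feature {f.name}) not in genome")
        n = len(genome[f.chrom])
        if f.strand == "+":
            g0, g1 = f.end - window.upstream_nt, f.end + window.downstream_nt
            seq = _fetch(genome, f.chrom, g0, g1)
            first = max(g0, 0) - f.end
        else:
            g0, g1 = f.start - window.downstream_nt, f.start + window.upstream_nt
            seq = reverse_complement(_fetch(genome, f.chrom, g0, g1))
            # oriented position 0 = base at genomic start-1; clipping at the
            # chromosome *right* end trims the upstream side after revcomp
            first = f.start - min(g1, n)
        clipped = len(seq) < window.upstream_nt + window.downstream_nt
        out.append(OrientedWindow(name=f.name, seq=seq, first_position=first,
                                  clipped=clipped))
    return out


@dataclass
class PositionalProfile:
    positions: np.ndarray      # oriented start positions
    counts: np.ndarray         # motif occurrences starting at each position
    coverage: np.ndarray       # features whose window fully covers the k-mer
    motif: str
    k: int

    @property
    def density(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(self.coverage > 0, self.counts / self.coverage, 0.0)
        return d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": self.positions,
            "count": self.counts,
            "coverage": self.coverage,
            "density": self.density,
        })


def positional_profile(
    windows: Sequence[OrientedWindow],
    motif: str,
    window: Window = Window(),
) -> PositionalProfile:
    """Count motif occurrence starts per oriented position across windows.

    Every overlapping occurrence is counted; any k-mer containing a non-ACGT
    base matches nothing.  Per-position coverage is the number of windows in
    which the full k-mer starting there lies inside the (clipped) sequence, so
    edge clipping does not masquerade as depletion in the density.
    """
    m = normalize_motif(motif)
    k = len(m)
    lo, hi = -window.upstream_nt, window.downstream_nt - k
    positions = np.arange(lo, hi + 1)
    counts = np.zeros(len(positions), dtype=int)
    coverage = np.zeros(len(positions), dtype=int)
    for w in windows:
        start_lo = w.first_position
        start_hi = w.first_position + len(w.seq) - k
        for pi, p in enumerate(positions):
            if start_lo <= p <= start_hi:
                coverage[pi] += 1
                if w.seq[p - w.first_position: p - w.first_position + k] == m:
                    counts[pi] += 1
    return PositionalProfile(positions=positions, counts=counts,
                             coverage=coverage, motif=m, k=k)


@dataclass
class KmerRanking:
    k: int
    table: list[tuple[str, int]]   # descending count, lexicographic tie-break

    def rank(self, kmer: str) -> int:
        """Strict 1-based rank in the tie-broken ordering."""
        m = normalize_motif(kmer)
        for i, (km, _) in enumerate(self.table, start=1):
            if km == m:
                return i
        raise KeyError(f"{kmer!r} not observed")

    def count_rank(self, kmer: str) -> int:
        """Dense rank of the k-mer's count value (ties share a rank)."""
        m = normalize_motif(kmer)
        counts = sorted({c for _, c in self.table}, reverse=True)
        target = dict(self.table).get(m)
        if target is None:
            raise KeyError(f"{kmer!r} not observed")
        return counts.index(target) + 1

    def count(self, kmer: str) -> int:
        return dict(self.table).get(normalize_motif(kmer), 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i, km, c) for i, (km, c) in enumerate(self.table, start=1)],
            columns=["rank", "kmer", "count"],
        )


def rank_kmers(windows: Sequence[OrientedWindow], k: int) -> KmerRanking:
    """Frequency ranking of all overlapping k-mers across oriented windows.

    k-mers containing non-ACGT characters are skipped entirely.  Ties in count
    are broken lexicographically for a strict ordering; ``count_rank`` gives
    the tie-sharing rank of a count value.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counter: Counter[str] = Counter()
    for w in windows:
        s = w.seq
        for i in range(len(s) - k + 1):
            km = s[i:i + k]
            if all(c in "ACGT" for c in km):
                counter[km] += 1
    table = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return KmerRanking(k=k, table=table)


def smooth_profile(profile: PositionalProfile, width: int) -> PositionalProfile:
    """Centered moving average of the density (width 1 = identity).

    Returns a profile whose counts/coverage are replaced by the smoothed
    density in ``counts`` with unit coverage, since smoothed counts are no
    longer integers.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be odd and >= 1")
    d = profile.density
    if width == 1:
        sm = d.copy()
    else:
        kernel = np.ones(width) / width
        # edge-aware: normalize by the in-range kernel mass
        sm = np.convolve(d, kernel, mode="same")
        norm = np.convolve(np.ones_like(d), kernel, mode="same")
        sm = sm / norm
    return PositionalProfile(
        positions=profile.positions.copy(), counts=sm,
        coverage=np.ones_like(profile.coverage), motif=profile.motif,
        k=profile.k,
    )


# ---------------------------------------------------------------- file I/O

def read_bed6(path) -> FeatureSet:
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            feats.append(Feature(
                chrom=parts[0], start=int(parts[1]), end=int(parts[2]),
                name=parts[3] if len(parts) > 3 else ".",
                strand=parts[5] if len(parts) > 5 else "+",
            ))
    return FeatureSet(feats)


def write_bed6(features: FeatureSet, path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.name}\t0\t{f.strand}\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def ensembl_tsv_to_features(path, biotype: str = "snRNA") -> FeatureSet:
    """Convert an Ensembl-style gene TSV export (chrom, start, end, strand,
    biotype[, name]) to a FeatureSet, keeping only the requested biotype.
    Ensembl exports are 1-based inclusive; converted to 0-based half-open.
    Strand may be +/- or 1/-1."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    feats = []
    for _, row in df.iterrows():
        if str(row[cols["biotype"]]) != biotype:
            continue
        strand_raw = str(row[cols["strand"]])
        strand = "+" if strand_raw in ("+", "1") else "-"
        feats.append(Feature(
            chrom=str(row[cols["chrom"]]),
            start=int(row[cols["start"]]) - 1,
            end=int(row[cols["end"]]),
            strand=strand,
            name=str(row[cols["name"]]) if "name" in cols else ".",
        ))
    return FeatureSet(feats)
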