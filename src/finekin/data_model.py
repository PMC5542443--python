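"""Domain types and I/O for georeferenced multilocus genotype data.

The containers here carry everything downstream analyses need: diploid
microsatellite (SSR) genotypes with missing-data support, per-individual
spatial metadata (planar coordinates in metres, optional altitude and
morphotype), and maternally inherited plastid haplotypes, either supplied
as labels or called from an aligned *psbA-trnH* FASTA by combining
nucleotide substitutions, indels (each gap-run extent coded as a single
character state) and user-declared inversion regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

MISSING = None

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "SpatialFrame",
    "HaplotypeSet",
    "AltitudeClasses",
    "LoadReport",
    "JoinedDataset",
    "read_genotypes",
    "write_genotypes",
    "read_coords",
    "call_haplotypes",
    "join_dataset",
    "lonlat_to_metres",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Diploid multilocus genotypes.

    ``calls[i][l]`` is an unordered pair of allele labels (stored as a
    sorted tuple of strings) or ``None`` for missing. Allele labels are
    preserved verbatim; integer repeat sizes are just strings here.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    calls: list[list[tuple[str, str] | None]]

    def __post_init__(self) -> None:
        if len(self.individual_ids) < 2:
            raise ValueError("need at least 2 individuals")
        if len(self.locus_ids) < 1:
            raise ValueError("need at least 1 locus")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicated individual id")
        for i, row in enumerate(self.calls):
            if len(row) != len(self.locus_ids):
                raise ValueError(f"row {self.individual_ids[i]!r} has wrong length")
            self.calls[i] = [
                None if c is None else tuple(sorted(str(a) for a in c)) for c in row
            ]
            for c in self.calls[i]:
                if c is not None and len(c) != 2:
                    raise ValueError("non-missing call must have exactly 2 alleles")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def locus_index(self, locus: str) -> int:
        return self.locus_ids.index(locus)

    def alleles_at(self, locus: int) -> list[str]:
        """Sorted distinct allele labels observed at a locus."""
        seen = set()
        for row in self.calls:
            c = row[locus]
            if c is not None:
                seen.update(c)
        return sorted(seen)

    def allele_counts(self, locus: int) -> dict[str, int]:
        """Gene-copy counts per allele at a locus (missing excluded)."""
        counts: dict[str, int] = {}
        for row in self.calls:
            c = row[locus]
            if c is not None:
                for a in c:
                    counts[a] = counts.get(a, 0) + 1
        return counts

    def gene_copies(self, locus: int) -> int:
        return sum(self.allele_counts(locus).values())

    def missing_fraction(self, locus: int) -> float:
        miss = sum(1 for row in self.calls if row[locus] is None)
        return miss / self.n_individuals

    def dosage_matrix(self, locus: int) -> tuple[np.ndarray, list[str]]:
        """(n, n_alleles) dosage in {0, 0.5, 1}; NaN rows where missing."""
        alleles = self.alleles_at(locus)
        idx = {a: j for j, a in enumerate(alleles)}
        X = np.full((self.n_individuals, len(alleles)), np.nan)
        for i, row in enumerate(self.calls):
            c = row[locus]
            if c is not None:
                X[i] = 0.0
                for a in c:
                    X[i, idx[a]] += 0.5
        return X, alleles

    def subset(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {g: i for i, g in enumerate(self.individual_ids)}
        rows = [self.calls[pos[g]] for g in ids]
        return GenotypeMatrix(list(ids), list(self.locus_ids), [list(r) for r in rows])

    def drop_locus(self, locus: int) -> "GenotypeMatrix":
        keep = [l for l in range(self.n_loci) if l != locus]
        return GenotypeMatrix(
            list(self.individual_ids),
            [self.locus_ids[l] for l in keep],
            [[row[l] for l in keep] for row in self.calls],
        )


@dataclass
class SpatialFrame:
    """Per-individual spatial metadata; coordinates are planar metres."""

    individual_ids: list[str]
    x: np.ndarray
    y: np.ndarray
    altitude: np.ndarray | None = None
    morphotype: list[str | None] | None = None
    population: list[str] | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.individual_ids)
        if self.x.shape != (n,) or self.y.shape != (n,):
            raise ValueError("coordinate arrays must match individual_ids")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("coordinates must be finite")
        if self.altitude is not None:
            self.altitude = np.asarray(self.altitude, dtype=float)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def distances(self) -> np.ndarray:
        dx = self.x[:, None] - self.x[None, :]
        dy = self.y[:, None] - self.y[None, :]
        return np.hypot(dx, dy)

    def subset(self, ids: Sequence[str]) -> "SpatialFrame":
        pos = {g: i for i, g in enumerate(self.individual_ids)}
        sel = [pos[g] for g in ids]
        return SpatialFrame(
            list(ids),
            self.x[sel],
            self.y[sel],
            None if self.altitude is None else self.altitude[sel],
            None if self.morphotype is None else [self.morphotype[i] for i in sel],
            None if self.population is None else [self.population[i] for i in sel],
        )


@dataclass
class HaplotypeSet:
    """One maternally inherited haplotype label per individual (or None)."""

    individual_ids: list[str]
    labels: list[str | None]
    variant_positions: list[int] | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.individual_ids):
            raise ValueError("labels must match individual_ids")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for h in self.labels:
            if h is not None:
                out[h] = out.get(h, 0) + 1
        return out

    def subset(self, ids: Sequence[str]) -> "HaplotypeSet":
        pos = {g: i for i, g in enumerate(self.individual_ids)}
        return HaplotypeSet(list(ids), [self.labels[pos[g]] for g in ids])


@dataclass
class AltitudeClasses:
    """Altitude partitioned into 3 classes by 2 cut points (default terciles)."""

    cut_points: tuple[float, float]
    class_index: np.ndarray  # 0/1/2 per individual, -1 if altitude missing

    @classmethod
    def from_altitudes(
        cls, altitude: np.ndarray, cut_points: tuple[float, float] | None = None
    ) -> "AltitudeClasses":
        alt = np.asarray(altitude, dtype=float)
        ok = np.isfinite(alt)
        if cut_points is None:
            c1, c2 = np.quantile(alt[ok], [1 / 3, 2 / 3])
            cut_points = (float(c1), float(c2))
        idx = np.full(alt.shape, -1, dtype=int)
        idx[ok] = np.digitize(alt[ok], cut_points)
        return cls(cut_points, idx)


@dataclass
class LoadReport:
    n_individuals: int
    n_loci: int
    missing_pct: dict[str, float] = field(default_factory=dict)


@dataclass
class JoinedDataset:
    genotypes: GenotypeMatrix | None
    spatial: SpatialFrame | None
    haplotypes: HaplotypeSet | None
    dropped: dict[str, list[str]] = field(default_factory=dict)

    @property
    def individual_ids(self) -> list[str]:
        for part in (self.genotypes, self.spatial, self.haplotypes):
            if part is not None:
                return part.individual_ids
        return []


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _split_call(token: str, missing: str) -> tuple[str, str] | None:
    token = token.strip()
    if token == missing:
        return None
    a, b = token.split("/")
    a, b = a.strip(), b.strip()
    if a == missing.split("/")[0] and b == a:
        return None
    return (a, b)


def read_genotypes(
    path: str | Path,
    *,
    sep: str = "\t",
    missing: str = "0",
    id_column: str | int = 0,
    locus_columns: Mapping[str, Sequence[str]] | None = None,
) -> tuple[GenotypeMatrix, LoadReport]:
    """Read a delimited genotype table.

    One row per individual. Loci come either as one column holding "a/b"
    calls, or as two columns per locus declared through *locus_columns*
    (``{"Sg03": ["Sg03_1", "Sg03_2"], ...}``). A call is missing when the
    token (or both halves of a pair) equals *missing*; "0/0" with the
    default token is missing too.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    idcol = df.columns[id_column] if isinstance(id_column, int) else id_column
    ids = [str(v) for v in df[idcol]]
    if len(set(ids)) != len(ids):
        dup = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicated individual id(s): {dup}")

    calls: list[list[tuple[str, str] | None]] = []
    if locus_columns is not None:
        loci = list(locus_columns)
        for _, row in df.iterrows():
            rec = []
            for locus in loci:
                c1, c2 = locus_columns[locus]
                a, b = str(row[c1]).strip(), str(row[c2]).strip()
                rec.append(None if missing in (a, b) else (a, b))
            calls.append(rec)
    else:
        loci = [c for c in df.columns if c != idcol]
        for ridx, row in df.iterrows():
            rec = []
            for locus in loci:
                token = str(row[locus])
                if "/" not in token and token != missing:
                    raise ValueError(f"ragged or malformed row {ids[ridx]!r} at {locus!r}")
                if token == missing:
                    rec.append(None)
                else:
                    a, b = (t.strip() for t in token.split("/", 1))
                    rec.append(None if a == missing and b == missing else (a, b))
            calls.append(rec)

    g = GenotypeMatrix(ids, loci, calls)
    report = LoadReport(
        g.n_individuals,
        g.n_loci,
        {locus: 100.0 * g.missing_fraction(l) for l, locus in enumerate(loci)},
    )
    return g, report


def write_genotypes(
    g: GenotypeMatrix, path: str | Path, *, sep: str = "\t", missing: str = "0"
) -> None:
    """Canonical writer: id column plus one "a/b" column per locus."""
    with open(path, "w") as fh:
        fh.write(sep.join(["id", *g.locus_ids]) + "\n")
        for gid, row in zip(g.individual_ids, g.calls):
            toks = [missing if c is None else f"{c[0]}/{c[1]}" for c in row]
            fh.write(sep.join([gid, *toks]) + "\n")


def lonlat_to_metres(lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local equirectangular projection about the centroid.

    Adequate for within-population extents of a few km where distortion
    is negligible; output is planar metres.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lat0, lon0 = lat.mean(), lon.mean()
    R = 6_371_000.0
    x = np.radians(lon - lon0) * R * math.cos(math.radians(lat0))
    y = np.radians(lat - lat0) * R
    return x, y


def read_coords(
    path: str | Path,
    *,
    sep: str = "\t",
    lonlat: bool = False,
) -> SpatialFrame:
    """Read a coordinate table with columns id, x, y [, altitude, morphotype,
    population]; with ``lonlat=True`` the x/y columns are lon/lat degrees and
    are projected to local metres."""
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    ids = [str(v) for v in df[cols.get("id", df.columns[0])]]
    x = df[cols["x"]].to_numpy(float)
    y = df[cols["y"]].to_numpy(float)
    if lonlat:
        x, y = lonlat_to_metres(x, y)
    alt = df[cols["altitude"]].to_numpy(float) if "altitude" in cols else None
    morph = (
        [None if pd.isna(v) else str(v) for v in df[cols["morphotype"]]]
        if "morphotype" in cols
        else None
    )
    pop = [str(v) for v in df[cols["population"]]] if "population" in cols else None
    return SpatialFrame(ids, x, y, alt, morph, pop)


# ---------------------------------------------------------------------------
# haplotype calling from an alignment
# ---------------------------------------------------------------------------


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, ch in enumerate(seq):
        if ch == "-" and start is None:
            start = i
        elif ch != "-" and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def call_haplotypes(
    alignment: str | Path | Sequence,
    inversion_regions: Iterable[tuple[int, int]] | None = None,
) -> HaplotypeSet:
    """Call haplotypes from an aligned FASTA (or SeqRecord sequence).

    Character states combined per individual: nucleotide substitutions at
    variable columns, each distinct gap-run extent as one presence/absence
    character (a 4-bp deletion is one state, not four), and the
    orientation of each user-declared inversion interval (forward vs
    reverse-complement of the first sequence's region). Labels H1, H2, ...
    are assigned by first occurrence.
    """
    if isinstance(alignment, (str, Path)):
        records = list(SeqIO.parse(str(alignment), "fasta"))
    else:
        records = list(alignment)
    if not records:
        raise ValueError("empty alignment")
    seqs = [str(r.seq).upper() for r in records]
    ids = [r.id for r in records]
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("aligned sequences must all have equal length")

    inv = sorted(tuple(r) for r in (inversion_regions or []))
    in_inv = np.zeros(L, dtype=bool)
    for a, b in inv:
        in_inv[a:b] = True

    # inversion-orientation states
    inv_states: list[list[str]] = []
    for a, b in inv:
        ref = seqs[0][a:b].replace("-", "")
        ref_rc = str(Seq(ref).reverse_complement())
        states = []
        for s in seqs:
            region = s[a:b].replace("-", "")
            if region == ref:
                states.append("F")
            elif region == ref_rc:
                states.append("R")
            else:
                states.append(region)  # distinct state of its own
        inv_states.append(states)

    # gap-run presence/absence, gaps inside inversion intervals excluded
    all_runs = sorted({run for s in seqs for run in _gap_runs(s) if not in_inv[run[0]]})
    run_states = [
        ["1" if run in set(_gap_runs(s)) else "0" for s in seqs] for run in all_runs
    ]

    # substitution columns: variable non-gap columns outside inversions
    var_cols = []
    for j in range(L):
        if in_inv[j]:
            continue
        col = {s[j] for s in seqs if s[j] != "-"}
        if len(col) > 1:
            var_cols.append(j)

    keys = []
    for i, s in enumerate(seqs):
        subs = tuple(s[j] for j in var_cols)
        gaps = tuple(states[i] for states in run_states)
        invs = tuple(states[i] for states in inv_states)
        keys.append((subs, gaps, invs))

    label_of: dict = {}
    labels = []
    for k in keys:
        if k not in label_of:
            label_of[k] = f"H{len(label_of) + 1}"
        labels.append(label_of[k])
    return HaplotypeSet(ids, labels, variant_positions=var_cols)


# ---------------------------------------------------------------------------
# join
# ---------------------------------------------------------------------------


def join_dataset(
    g: GenotypeMatrix | None,
    s: SpatialFrame | None,
    h: HaplotypeSet | None = None,
) -> JoinedDataset:
    """Inner-join the parts on individual id; dropped ids are reported.

    Parts may be None (e.g. plastid-only data); at least one is required
    and the id intersection across supplied parts must be non-empty.
    """
    parts = {"genotypes": g, "spatial": s, "haplotypes": h}
    supplied = {k: v for k, v in parts.items() if v is not None}
    if not supplied:
        raise ValueError("nothing to join")
    idsets = {k: set(v.individual_ids) for k, v in supplied.items()}
    common = set.intersection(*idsets.values())
    if not common:
        raise ValueError("empty id intersection across supplied parts")
    first = next(iter(supplied.values()))
    order = [gid for gid in first.individual_ids if gid in common]
    dropped = {k: sorted(ids - common) for k, ids in idsets.items() if ids - common}
    return JoinedDataset(
        g.subset(order) if g is not None else None,
        s.subset(order) if s is not None else None,
        h.subset(order) if h is not None else None,
        dropped,
    )
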