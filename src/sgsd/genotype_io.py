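"""Genotype tables: data model, readers/writers, sample-level QC and spatial helpers.

The central container is :class:`GenotypeTable`, a diploid multilocus genotype
matrix with per-sample coordinates and optional group labels. Every analysis
module consumes it. Two text formats are supported: a documented CSV dialect
(``sample_id,x,y,group,<locus>_1,<locus>_2,...``) and the SPAGeDi text format;
a STRUCTURE-format exporter is provided for interoperability.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

#: Internal missing-allele sentinel, distinct from any valid (positive) allele state.
MISSING = -1

#: Sphere radius used for great-circle distances, in meters.
EARTH_RADIUS_M = 6_371_000.0


class GenotypeFormatError(ValueError):
    """An input file violates the declared dialect or a table invariant."""


@dataclass
class GenotypeTable:
    """Diploid multilocus genotypes with coordinates and optional group labels.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per row.
    x, y
        Coordinates. Planar mode: meters. Geographic mode: x = longitude,
        y = latitude, decimal degrees.
    groups
        Object array of group labels (``None`` for unlabelled samples).
    loci
        Ordered, unique locus names.
    genotypes
        Integer array of shape ``(n_samples, n_loci, 2)``. Allele states are
        positive integers (sizes in bp or repeat units); a missing genotype has
        :data:`MISSING` in *both* slots. Allele pairs are unordered.
    coord_system
        ``"planar"`` or ``"geographic"``.
    """

    sample_ids: list
    x: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    loci: list
    genotypes: np.ndarray
    coord_system: str = "planar"
    ploidy: int = 2

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.loci = list(self.loci)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.groups = np.asarray(self.groups, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        n, L = len(self.sample_ids), len(self.loci)
        if self.coord_system not in ("planar", "geographic"):
            raise GenotypeFormatError(
                f"coord_system must be 'planar' or 'geographic', got {self.coord_system!r}"
            )
        if self.ploidy != 2:
            raise GenotypeFormatError("only diploid tables are supported")
        if len(set(self.loci)) != L:
            raise GenotypeFormatError("locus names must be unique")
        if len(set(self.sample_ids)) != n:
            seen, dups = set(), set()
            for s in self.sample_ids:
                (dups if s in seen else seen).add(s)
            raise GenotypeFormatError(f"duplicate sample_id(s): {sorted(dups)}")
        if self.genotypes.shape != (n, L, 2):
            raise GenotypeFormatError(
                f"genotypes shape {self.genotypes.shape} != ({n}, {L}, 2)"
            )
        for arr, name in ((self.x, "x"), (self.y, "y"), (self.groups, "groups")):
            if arr.shape != (n,):
                raise GenotypeFormatError(f"{name} must have length {n}")
        g = self.genotypes
        half_missing = (g == MISSING).sum(axis=2) == 1
        if half_missing.any():
            i, l = np.argwhere(half_missing)[0]
            raise GenotypeFormatError(
                f"sample {self.sample_ids[i]!r}, locus {self.loci[l]!r}: "
                "a genotype must be fully missing or have both alleles"
            )
        bad = (g != MISSING) & (g <= 0)
        if bad.any():
            i, l, _ = np.argwhere(bad)[0]
            raise GenotypeFormatError(
                f"sample {self.sample_ids[i]!r}, locus {self.loci[l]!r}: "
                "allele states must be positive integers"
            )

    # ------------------------------------------------------------------ views

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def typed(self) -> np.ndarray:
        """Boolean ``(n_samples, n_loci)`` mask of non-missing genotypes."""
        return self.genotypes[:, :, 0] != MISSING

    def subset(self, idx) -> "GenotypeTable":
        """Row subset (order as given by ``idx``)."""
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            x=self.x[idx],
            y=self.y[idx],
            groups=self.groups[idx],
            loci=self.loci,
            genotypes=self.genotypes[idx],
            coord_system=self.coord_system,
        )

    def select_group(self, group) -> "GenotypeTable":
        mask = np.array([g == group for g in self.groups])
        if not mask.any():
            raise ValueError(f"group {group!r} selects no samples")
        return self.subset(mask)

    def group_labels(self) -> list:
        """Distinct non-None group labels, in first-appearance order."""
        out = []
        for g in self.groups:
            if g is not None and g not in out:
                out.append(g)
        return out

    def with_groups(self, groups) -> "GenotypeTable":
        return replace(self, groups=np.asarray(list(groups), dtype=object))

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.loci == other.loci
            and self.coord_system == other.coord_system
            and np.allclose(self.x, other.x)
            and np.allclose(self.y, other.y)
            and all(a == b for a, b in zip(self.groups, other.groups))
            and np.array_equal(
                np.sort(self.genotypes, axis=2), np.sort(other.genotypes, axis=2)
            )
        )


@dataclass
class AlleleFrequencies:
    """Per-locus allele frequencies over non-missing gene copies.

    ``freqs[l]`` maps allele state -> relative frequency at locus ``loci[l]``;
    ``counts[l]`` maps allele state -> observed copy count; ``n_copies[l]`` is
    the number of gene copies actually observed. Loci with zero typed copies
    are listed in ``untyped_loci`` and carry empty maps.
    """

    loci: list
    freqs: list
    counts: list
    n_copies: np.ndarray
    untyped_loci: list = field(default_factory=list)

    def __post_init__(self):
        self.n_copies = np.asarray(self.n_copies, dtype=np.int64)
        for l, f in enumerate(self.freqs):
            if f and abs(sum(f.values()) - 1.0) > 1e-9:
                raise ValueError(f"frequencies at locus {self.loci[l]!r} do not sum to 1")

    def alleles(self, l: int) -> np.ndarray:
        return np.array(sorted(self.freqs[l]), dtype=np.int64)


# ---------------------------------------------------------------------- I/O


def read_genotypes(path, format: str = "csv", coord_system: str = "planar") -> GenotypeTable:
    """Read a genotype table from ``path``.

    ``format`` is ``"csv"`` (primary dialect) or ``"spagedi"``. ``coord_system``
    is used when the file does not declare one (the CSV writer emits a
    ``# coord_system:`` comment line; SPAGeDi encodes lat/lon as a negative
    coordinate count).
    """
    path = Path(path)
    if format == "csv":
        return _read_csv(path, coord_system)
    if format == "spagedi":
        return _read_spagedi(path, coord_system)
    raise ValueError(f"unknown format {format!r}")


def write_genotypes(table: GenotypeTable, path, format: str = "csv") -> None:
    path = Path(path)
    if format == "csv":
        _write_csv(table, path)
    elif format == "spagedi":
        _write_spagedi(table, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _parse_allele(token: str, line_no: int, sample_id: str):
    token = token.strip()
    if token == "" or token == "0":
        return MISSING
    try:
        a = int(token)
    except ValueError:
        raise GenotypeFormatError(
            f"line {line_no}, sample {sample_id!r}: bad allele value {token!r}"
        ) from None
    if a < 0:
        raise GenotypeFormatError(
            f"line {line_no}, sample {sample_id!r}: negative allele {a}"
        )
    return a if a > 0 else MISSING


def _read_csv(path: Path, coord_system: str) -> GenotypeTable:
    with open(path, newline="", encoding="utf-8") as fh:
        line_no = 0
        header = None
        rows = []
        reader = csv.reader(fh)
        for rec in reader:
            line_no += 1
            if not rec or (rec[0].startswith("#") and header is None):
                if rec and rec[0].startswith("# coord_system:"):
                    coord_system = rec[0].split(":", 1)[1].strip()
                continue
            if header is None:
                header = rec
            else:
                rows.append((line_no, rec))
    if header is None:
        raise GenotypeFormatError(f"{path}: empty file")
    fixed = ["sample_id", "x", "y", "group"]
    if [h.strip() for h in header[:4]] != fixed:
        raise GenotypeFormatError(
            f"{path}: header must start with {','.join(fixed)}"
        )
    locus_cols = [h.strip() for h in header[4:]]
    if len(locus_cols) % 2 != 0:
        raise GenotypeFormatError(f"{path}: odd number of allele columns")
    loci = []
    for i in range(0, len(locus_cols), 2):
        a, b = locus_cols[i], locus_cols[i + 1]
        if not (a.endswith("_1") and b.endswith("_2") and a[:-2] == b[:-2]):
            raise GenotypeFormatError(
                f"{path}: allele columns {a!r},{b!r} are not a <locus>_1,<locus>_2 pair"
            )
        loci.append(a[:-2])

    ids, xs, ys, grps, genos = [], [], [], [], []
    for line_no, rec in rows:
        if len(rec) != len(header):
            raise GenotypeFormatError(
                f"{path} line {line_no}: expected {len(header)} fields, got {len(rec)}"
            )
        sid = rec[0].strip()
        try:
            x, y = float(rec[1]), float(rec[2])
        except ValueError:
            raise GenotypeFormatError(
                f"{path} line {line_no}, sample {sid!r}: bad coordinate"
            ) from None
        grp = rec[3].strip() or None
        row = []
        for l, locus in enumerate(loci):
            a1 = _parse_allele(rec[4 + 2 * l], line_no, sid)
            a2 = _parse_allele(rec[5 + 2 * l], line_no, sid)
            if (a1 == MISSING) != (a2 == MISSING):
                raise GenotypeFormatError(
                    f"{path} line {line_no}, sample {sid!r}, locus {locus!r}: "
                    "exactly one allele missing"
                )
            row.append((a1, a2))
        if sid in set(ids):
            raise GenotypeFormatError(
                f"{path} line {line_no}: duplicate sample_id {sid!r}"
            )
        ids.append(sid)
        xs.append(x)
        ys.append(y)
        grps.append(grp)
        genos.append(row)
    return GenotypeTable(
        sample_ids=ids,
        x=np.array(xs),
        y=np.array(ys),
        groups=np.array(grps, dtype=object),
        loci=loci,
        genotypes=np.array(genos, dtype=np.int64).reshape(len(ids), len(loci), 2),
        coord_system=coord_system,
    )


def _write_csv(table: GenotypeTable, path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow([f"# coord_system: {table.coord_system}"])
        w.writerow(
            ["sample_id", "x", "y", "group"]
            + [f"{loc}_{i}" for loc in table.loci for i in (1, 2)]
        )
        for i, sid in enumerate(table.sample_ids):
            row = [sid, repr(float(table.x[i])), repr(float(table.y[i])),
                   table.groups[i] if table.groups[i] is not None else ""]
            for l in range(table.n_loci):
                a1, a2 = table.genotypes[i, l]
                row += ["" if a1 == MISSING else str(int(a1)),
                        "" if a2 == MISSING else str(int(a2))]
            w.writerow(row)


def _read_spagedi(path: Path, coord_system: str) -> GenotypeTable:
    lines = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            s = raw.rstrip("\n")
            if s.strip().startswith("//") or not s.strip():
                continue
            lines.append(s)
    if not lines:
        raise GenotypeFormatError(f"{path}: empty file")
    head = lines[0].replace(",", "\t").split()
    if len(head) < 6:
        raise GenotypeFormatError(f"{path}: first line must carry 6 format numbers")
    n_ind, n_cat, n_coord, n_loci, n_digits, ploidy = (int(v) for v in head[:6])
    if ploidy != 2:
        raise GenotypeFormatError(f"{path}: ploidy {ploidy} unsupported (need 2)")
    if n_coord < 0:
        coord_system = "geographic"
        n_coord = -n_coord
    if n_coord not in (0, 2):
        raise GenotypeFormatError(f"{path}: {n_coord} coordinate columns unsupported")
    # second line: distance-class specification (ignored); third: column names
    header = lines[2].replace(",", "\t").split()
    loci = header[1 + (1 if n_cat else 0) + n_coord:]
    if len(loci) != n_loci:
        raise GenotypeFormatError(
            f"{path}: header names {len(loci)} loci, first line declares {n_loci}"
        )
    ids, xs, ys, grps, genos = [], [], [], [], []
    for line_no, line in enumerate(lines[3:], start=4):
        if line.strip().upper() == "END":
            break
        rec = line.replace(",", "\t").split()
        sid = rec[0]
        pos = 1
        grp = None
        if n_cat:
            # "NA" is the writer's placeholder for unlabelled samples
            grp = None if rec[pos] == "NA" else rec[pos]
            pos += 1
        if n_coord:
            if coord_system == "geographic":
                # SPAGeDi convention: latitude column first, then longitude
                y, x = float(rec[pos]), float(rec[pos + 1])
            else:
                x, y = float(rec[pos]), float(rec[pos + 1])
            pos += 2
        else:
            x = y = 0.0
        if len(rec) - pos != n_loci:
            raise GenotypeFormatError(
                f"{path} line {line_no}, sample {sid!r}: expected {n_loci} genotype "
                f"columns, got {len(rec) - pos}"
            )
        row = []
        for l in range(n_loci):
            token = rec[pos + l]
            if "/" in token:
                parts = token.split("/")
                if len(parts) != 2:
                    raise GenotypeFormatError(
                        f"{path} line {line_no}, sample {sid!r}: bad genotype {token!r}"
                    )
                a1s, a2s = parts
            else:
                token = token.zfill(2 * n_digits)
                if len(token) != 2 * n_digits:
                    raise GenotypeFormatError(
                        f"{path} line {line_no}, sample {sid!r}: genotype {token!r} "
                        f"longer than {2 * n_digits} digits"
                    )
                a1s, a2s = token[:n_digits], token[n_digits:]
            a1 = _parse_allele(a1s.lstrip("0") or "0", line_no, sid)
            a2 = _parse_allele(a2s.lstrip("0") or "0", line_no, sid)
            if (a1 == MISSING) != (a2 == MISSING):
                raise GenotypeFormatError(
                    f"{path} line {line_no}, sample {sid!r}, locus {loci[l]!r}: "
                    "exactly one allele missing"
                )
            row.append((a1, a2))
        if sid in set(ids):
            raise GenotypeFormatError(f"{path} line {line_no}: duplicate sample_id {sid!r}")
        ids.append(sid)
        xs.append(x)
        ys.append(y)
        grps.append(grp)
        genos.append(row)
    if len(ids) != n_ind:
        warnings.warn(
            f"{path}: first line declares {n_ind} individuals, found {len(ids)}"
        )
    return GenotypeTable(
        sample_ids=ids,
        x=np.array(xs),
        y=np.array(ys),
        groups=np.array(grps, dtype=object),
        loci=list(loci),
        genotypes=np.array(genos, dtype=np.int64).reshape(len(ids), len(loci), 2),
        coord_system=coord_system,
    )


def _write_spagedi(table: GenotypeTable, path: Path) -> None:
    has_cat = any(g is not None for g in table.groups)
    g = table.genotypes
    max_allele = int(g.max()) if (g != MISSING).any() else 1
    n_digits = max(2, len(str(max_allele)))
    n_coord = -2 if table.coord_system == "geographic" else 2
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("// written by sgsd\n")
        fh.write(
            f"{table.n_samples}\t{1 if has_cat else 0}\t{n_coord}\t"
            f"{table.n_loci}\t{n_digits}\t2\n"
        )
        fh.write("0\n")
        cols = ["Ind"] + (["Cat"] if has_cat else [])
        cols += ["Lat", "Lon"] if table.coord_system == "geographic" else ["X", "Y"]
        cols += table.loci
        fh.write("\t".join(cols) + "\n")
        for i, sid in enumerate(table.sample_ids):
            rec = [str(sid)]
            if has_cat:
                rec.append(str(table.groups[i]) if table.groups[i] is not None else "NA")
            if table.coord_system == "geographic":
                rec += [repr(float(table.y[i])), repr(float(table.x[i]))]
            else:
                rec += [repr(float(table.x[i])), repr(float(table.y[i]))]
            for l in range(table.n_loci):
                a1, a2 = g[i, l]
                s1 = "0" * n_digits if a1 == MISSING else str(int(a1)).zfill(n_digits)
                s2 = "0" * n_digits if a2 == MISSING else str(int(a2)).zfill(n_digits)
                rec.append(s1 + s2)
            fh.write("\t".join(rec) + "\n")
        fh.write("END\n")


def write_structure(table: GenotypeTable, path) -> None:
    """Export in STRUCTURE format: two rows per individual, -9 for missing."""
    labels = {g: i + 1 for i, g in enumerate(table.group_labels())}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(table.loci) + "\n")
        for i, sid in enumerate(table.sample_ids):
            pop = labels.get(table.groups[i], 0)
            for slot in (0, 1):
                rec = [str(sid), str(pop)]
                for l in range(table.n_loci):
                    a = table.genotypes[i, l, slot]
                    rec.append("-9" if a == MISSING else str(int(a)))
                fh.write("\t".join(rec) + "\n")


# ------------------------------------------------------------------------ QC


def filter_min_typed_loci(table: GenotypeTable, min_fraction: float = 0.6) -> GenotypeTable:
    """Retain samples typed at ≥ ``min_fraction`` of loci (order preserved)."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    frac = table.typed().mean(axis=1)
    keep = frac >= min_fraction - 1e-12
    if not keep.any():
        warnings.warn("filter_min_typed_loci removed every sample")
    return table.subset(keep)


@dataclass
class DuplicatePair:
    sample_1: str
    sample_2: str
    shared_loci: int
    identical: bool
    coefficient: float  # proportion of shared alleles, averaged over shared loci


def relationship_coefficient(g1: np.ndarray, g2: np.ndarray):
    """Proportion of shared alleles between two genotype rows ``(n_loci, 2)``.

    Returns ``(coefficient, n_shared_loci)``; the coefficient averages, over
    loci typed in both samples, the fraction of alleles in common (counting
    multiplicity: 0, 0.5 or 1 per locus).
    """
    typed = (g1[:, 0] != MISSING) & (g2[:, 0] != MISSING)
    n_shared = int(typed.sum())
    if n_shared == 0:
        return np.nan, 0
    props = []
    for l in np.flatnonzero(typed):
        a = sorted(g1[l])
        b = sorted(g2[l])
        if a == b:
            props.append(1.0)
        elif a[0] in b or a[1] in b:
            props.append(0.5)
        else:
            props.append(0.0)
    return float(np.mean(props)), n_shared


def detect_duplicates(
    table: GenotypeTable, min_shared_loci: int = 5, return_all: bool = False
):
    """Find putative duplicated individuals.

    Returns the list of :class:`DuplicatePair` whose genotypes are identical
    at every locus typed in both samples, provided at least ``min_shared_loci``
    such loci exist. With ``return_all=True``, every pair with ≥1 shared locus
    is returned (``identical`` flags the exact matches), so callers can apply
    their own relatedness cutoff.
    """
    if table.n_samples == 0:
        raise ValueError("empty table")
    out = []
    g = table.genotypes
    gs = np.sort(g, axis=2)
    for i in range(table.n_samples):
        for j in range(i + 1, table.n_samples):
            coeff, n_shared = relationship_coefficient(g[i], g[j])
            if n_shared == 0:
                continue
            typed = (g[i][:, 0] != MISSING) & (g[j][:, 0] != MISSING)
            ident = bool(np.array_equal(gs[i][typed], gs[j][typed]))
            pair = DuplicatePair(
                table.sample_ids[i], table.sample_ids[j], n_shared,
                ident and n_shared >= min_shared_loci, coeff,
            )
            if pair.identical or return_all:
                out.append(pair)
    return out


def grid_subsample(
    table: GenotypeTable,
    cell_size: float = 0.01,
    max_per_cell: int = 3,
    seed: Optional[int] = None,
) -> GenotypeTable:
    """Cap the number of samples per square grid cell by seeded random draw.

    Cells are axis-aligned squares of side ``cell_size`` degrees anchored at
    (0°, 0°). Within any cell holding more than ``max_per_cell`` samples, a
    uniform random subset of ``max_per_cell`` is kept; sample order is
    preserved. Deterministic given ``seed``, and idempotent.
    """
    if table.coord_system != "planar" and table.coord_system != "geographic":
        raise ValueError("unknown coordinate system")
    if table.coord_system == "planar":
        raise ValueError(
            "grid_subsample expects geographic coordinates (cell size in degrees); "
            "got planar coordinates in meters"
        )
    if seed is None:
        raise ValueError("seed is required for reproducible subsampling")
    rng = np.random.default_rng(seed)
    cx = np.floor(table.x / cell_size).astype(np.int64)
    cy = np.floor(table.y / cell_size).astype(np.int64)
    cells = {}
    for i in range(table.n_samples):
        cells.setdefault((cx[i], cy[i]), []).append(i)
    keep = np.zeros(table.n_samples, dtype=bool)
    for key in sorted(cells):
        members = cells[key]
        if len(members) <= max_per_cell:
            keep[members] = True
        else:
            chosen = rng.choice(len(members), size=max_per_cell, replace=False)
            keep[[members[c] for c in chosen]] = True
    return table.subset(keep)


# ----------------------------------------------------------- shared statistics


def allele_frequencies(table: GenotypeTable, group=None) -> AlleleFrequencies:
    """Per-locus allele frequencies over non-missing gene copies.

    ``group`` optionally restricts to samples with that label. Loci with zero
    typed copies are flagged in ``untyped_loci`` (and excluded downstream).
    """
    t = table.select_group(group) if group is not None else table
    freqs, counts, n_copies, untyped = [], [], [], []
    for l, locus in enumerate(t.loci):
        g = t.genotypes[:, l, :]
        copies = g[g != MISSING]
        n = copies.size
        n_copies.append(n)
        if n == 0:
            untyped.append(locus)
            freqs.append({})
            counts.append({})
            continue
        vals, cnts = np.unique(copies, return_counts=True)
        counts.append({int(v): int(c) for v, c in zip(vals, cnts)})
        freqs.append({int(v): float(c) / n for v, c in zip(vals, cnts)})
    if untyped:
        warnings.warn(f"loci with zero typed copies: {untyped}")
    return AlleleFrequencies(
        loci=t.loci, freqs=freqs, counts=counts,
        n_copies=np.array(n_copies), untyped_loci=untyped,
    )


def pairwise_distances(table: GenotypeTable) -> np.ndarray:
    """Symmetric matrix of pairwise distances in meters.

    Planar coordinates: Euclidean. Geographic: great-circle (haversine on a
    sphere of radius 6,371,000 m).
    """
    bad = np.isnan(table.x) | np.isnan(table.y)
    if bad.any():
        raise ValueError(
            f"missing coordinate for sample {table.sample_ids[int(np.argmax(bad))]!r}"
        )
    if table.coord_system == "planar":
        dx = table.x[:, None] - table.x[None, :]
        dy = table.y[:, None] - table.y[None, :]
        return np.hypot(dx, dy)
    lon = np.radians(table.x)
    lat = np.radians(table.y)
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    )
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return d
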