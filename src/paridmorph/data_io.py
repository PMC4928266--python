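"""Readers and writers for every external format the pipeline touches.

Formats handled here:

* TPS landmark files (``LM=``, ``ID=``, ``IMAGE=``, ``SCALE=``, ``COMMENT=``
  records) as produced by the tpsDig family of digitising tools;
* plain coordinate matrices (one specimen per row, ``x1 y1 x2 y2 ...``), the
  layout in which aligned coordinates are usually deposited;
* delimited measurement tables (six linear traits, species, optional
  altitude);
* Newick trees with branch lengths (through :mod:`dendropy`);
* range tables: per-species area and altitudinal interval, plus a
  long-format pairwise overlap table.

All readers preserve record and point order exactly and never silently drop
or reorder data; malformed numeric cells in measurement tables become
explicitly flagged missing values (``None``), never zeros.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LandmarkConfiguration",
    "MeasurementRecord",
    "Phylogeny",
    "RangeRecord",
    "TpsParseError",
    "SchemaError",
    "paper_roles",
    "read_tps",
    "write_tps",
    "read_coordinate_matrix",
    "read_measurements",
    "write_measurements",
    "read_newick",
    "write_newick",
    "read_ranges",
    "write_ranges",
    "MEASUREMENT_TRAITS",
]

#: canonical trait column names, in canonical order
MEASUREMENT_TRAITS = (
    "body_weight",
    "body_length",
    "wing_length",
    "tail_length",
    "tarsus_length",
    "culmen_length",
)


class TpsParseError(ValueError):
    """Raised when a TPS file violates the record grammar."""


class SchemaError(ValueError):
    """Raised when a delimited table lacks mandatory columns."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class LandmarkConfiguration:
    """One specimen's 2-D landmark configuration.

    Parameters
    ----------
    specimen_id
        Identifier of the specimen (museum number or synthetic id).
    species
        Species label; may be empty when the source format carries none.
    points
        ``(k, 2)`` float array of landmark coordinates, order meaningful.
    roles
        Length-``k`` sequence of ``"fixed"`` / ``"semi"`` flags.
    scale_factor
        Optional positive scale (units per coordinate unit) as recorded in
        the source file; coordinates are stored already multiplied by it.
    """

    specimen_id: str
    species: str
    points: np.ndarray
    roles: tuple[str, ...]
    scale_factor: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be a (k, 2) array")
        if self.points.shape[0] < 3:
            raise ValueError("a configuration needs at least 3 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"non-finite coordinate in specimen {self.specimen_id!r}")
        self.roles = tuple(self.roles)
        if len(self.roles) != self.points.shape[0]:
            raise ValueError("roles and points must have equal length")
        bad = set(self.roles) - {"fixed", "semi"}
        if bad:
            raise ValueError(f"unknown point roles: {sorted(bad)}")
        if self.scale_factor is not None and not self.scale_factor > 0:
            raise ValueError("scale_factor must be positive")

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    @property
    def semi_mask(self) -> np.ndarray:
        """Boolean mask, True where a point is a sliding semilandmark."""
        return np.array([r == "semi" for r in self.roles])

    def equals(self, other: "LandmarkConfiguration", rtol: float = 1e-12) -> bool:
        return (
            self.specimen_id == other.specimen_id
            and self.species == other.species
            and self.roles == other.roles
            and self.points.shape == other.points.shape
            and np.allclose(self.points, other.points, rtol=rtol, atol=1e-300)
        )


@dataclass
class MeasurementRecord:
    """Six linear traits plus altitude for one specimen.

    Weights are in grams, lengths in millimetres, altitude in metres.
    A missing value is ``None`` (explicitly flagged), never zero.
    """

    specimen_id: str
    species: str
    body_weight: float | None = None
    body_length: float | None = None
    wing_length: float | None = None
    tail_length: float | None = None
    tarsus_length: float | None = None
    culmen_length: float | None = None
    altitude: float | None = None

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species label must be nonempty")
        for trait in MEASUREMENT_TRAITS:
            v = getattr(self, trait)
            if v is not None and not v > 0:
                raise ValueError(
                    f"{trait} must be strictly positive in specimen "
                    f"{self.specimen_id!r} (got {v!r})"
                )

    def trait_values(self) -> dict[str, float | None]:
        return {t: getattr(self, t) for t in MEASUREMENT_TRAITS}

    @property
    def complete(self) -> bool:
        """True when all six traits are present."""
        return all(getattr(self, t) is not None for t in MEASUREMENT_TRAITS)


@dataclass
class RangeRecord:
    """Geographic range area, pairwise overlaps and altitudinal interval."""

    species: str
    area: float
    pairwise_overlap: dict[str, float] = field(default_factory=dict)
    alt_min: float = 0.0
    alt_max: float = 0.0

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValueError(f"range area must be positive ({self.species})")
        if self.alt_min > self.alt_max:
            raise ValueError(f"alt_min > alt_max for {self.species}")
        for other, o in self.pairwise_overlap.items():
            if o < 0 or o > self.area + 1e-9:
                raise ValueError(
                    f"overlap O({self.species},{other})={o} outside [0, area]"
                )


class Phylogeny:
    """A rooted phylogeny with branch lengths, wrapping a dendropy tree.

    Tip labels must be unique; every edge carries a nonnegative length
    (edges without a length are assigned a caller-set default on read).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError("every edge must have a branch length")
            if edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")
        self._labels = labels

    # -- constructors -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, default_branch_length: float = 1.0) -> "Phylogeny":
        if text.count("(") != text.count(")"):
            raise ValueError("unbalanced parentheses in Newick string")
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:
            if "duplicate" in str(exc).lower() or "multiple occurrences" in str(exc).lower():
                raise ValueError(f"duplicate tip labels: {exc}") from exc
            raise ValueError(f"Newick parse error: {exc}") from exc
        filled = 0
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                edge.length = default_branch_length
                filled += 1
        if filled:
            logger.info(
                "assigned default branch length %g to %d edges",
                default_branch_length,
                filled,
            )
        return cls(tree)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return list(self._labels)

    @property
    def n_tips(self) -> int:
        return len(self._labels)

    def to_newick(self) -> str:
        return (
            self._tree.as_string(schema="newick", suppress_rooting=True).strip()
        )

    # -- structure ----------------------------------------------------

    def node_depths(self) -> dict[dendropy.Node, float]:
        """Distance of every node from the root."""
        depths: dict[dendropy.Node, float] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
        return depths

    def vcv(self) -> tuple[list[str], np.ndarray]:
        """Brownian-motion phylogenetic covariance matrix.

        ``C[i, j]`` is the root-to-MRCA path length of tips *i* and *j*;
        the diagonal holds tip depths.
        """
        depths = self.node_depths()
        labels = self.tip_labels
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        C = np.zeros((n, n))
        leafsets: dict[dendropy.Node, list[int]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                leafsets[node] = [index[node.taxon.label]]
                C[leafsets[node][0], leafsets[node][0]] = depths[node]
            else:
                children = [leafsets[c] for c in node.child_nodes()]
                for a in range(len(children)):
                    for b in range(a + 1, len(children)):
                        for i in children[a]:
                            for j in children[b]:
                                C[i, j] = C[j, i] = depths[node]
                leafsets[node] = [i for sub in children for i in sub]
        return labels, C

    def patristic_distances(self) -> tuple[list[str], np.ndarray]:
        """Tip-to-tip path lengths (sum of branch lengths)."""
        labels, C = self.vcv()
        d = np.diag(C)
        return labels, d[:, None] + d[None, :] - 2.0 * C

    def without_tips(self, drop: Iterable[str]) -> "Phylogeny":
        """A copy of the tree with the named tips pruned."""
        drop = set(drop)
        missing = drop - set(self._labels)
        if missing:
            raise ValueError(f"tips not in tree: {sorted(missing)}")
        clone = self._tree.clone(depth=1)
        taxa = [t for t in clone.taxon_namespace if t.label in drop]
        clone.prune_taxa(taxa)
        return Phylogeny(clone)


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------


def paper_roles(n_points: int) -> tuple[str, ...]:
    """Default role scheme: 3 fixed + 18 sliding for 21-point beak outlines
    (points 1-3 are the fixed landmarks), everything fixed otherwise."""
    if n_points == 21:
        return ("fixed",) * 3 + ("semi",) * 18
    return ("fixed",) * n_points


_KEYVAL = re.compile(r"^\s*([A-Za-z]+)\s*=\s*(.*?)\s*$")


def read_tps(
    path,
    roles=paper_roles,
    flip_y: bool = False,
) -> list[LandmarkConfiguration]:
    """Parse a TPS landmark file.

    Parameters
    ----------
    path
        TPS file path.
    roles
        Either a callable ``n_points -> roles tuple`` or an explicit tuple
        applied to every record.
    flip_y
        Negate y on read, for files digitised in image (y-down) coordinates.
    """
    text = Path(path).read_text()
    records: list[LandmarkConfiguration] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = _KEYVAL.match(line)
        if not m or m.group(1).upper() != "LM":
            raise TpsParseError(f"line {i + 1}: expected an LM= record header")
        try:
            n_pts = int(m.group(2))
        except ValueError:
            raise TpsParseError(f"line {i + 1}: bad landmark count {m.group(2)!r}")
        i += 1
        pts = []
        while i < len(lines) and len(pts) < n_pts:
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if _KEYVAL.match(row) and not _is_coordinate_line(row):
                break
            fields = row.split()
            if len(fields) != 2:
                raise TpsParseError(f"line {i + 1}: expected two coordinates")
            try:
                pts.append((float(fields[0]), float(fields[1])))
            except ValueError:
                raise TpsParseError(f"line {i + 1}: non-numeric coordinate")
            i += 1
        if len(pts) != n_pts:
            raise TpsParseError(
                f"record {len(records) + 1}: LM={n_pts} but only "
                f"{len(pts)} coordinate lines"
            )
        specimen_id = f"record_{len(records) + 1}"
        species = ""
        scale: float | None = None
        while i < len(lines):
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            m2 = _KEYVAL.match(row)
            if not m2 or m2.group(1).upper() == "LM":
                break
            key, val = m2.group(1).upper(), m2.group(2)
            if key == "ID":
                specimen_id = val
            elif key == "SCALE":
                scale = float(val)
            elif key == "COMMENT":
                species = val
            # IMAGE= and anything else: ignored by design
            i += 1
        points = np.asarray(pts, dtype=float)
        if flip_y:
            points[:, 1] *= -1.0
        if scale is not None:
            points = points * scale
        rec_roles = roles(n_pts) if callable(roles) else tuple(roles)
        records.append(
            LandmarkConfiguration(
                specimen_id=specimen_id,
                species=species,
                points=points,
                roles=rec_roles,
                scale_factor=scale,
            )
        )
    return records


def _is_coordinate_line(row: str) -> bool:
    fields = row.split()
    if len(fields) != 2:
        return False
    try:
        float(fields[0])
        float(fields[1])
    except ValueError:
        return False
    return True


def write_tps(configs: Sequence[LandmarkConfiguration], path) -> None:
    """Write configurations as a TPS file readable by :func:`read_tps`.

    Coordinates are emitted at full double precision. When a configuration
    carries a scale factor, coordinates are divided back and a ``SCALE=``
    line written, so a read/write cycle is the identity.
    """
    if not configs:
        raise ValueError("cannot write an empty configuration list")
    seen: set[str] = set()
    out: list[str] = []
    for cfg in configs:
        if cfg.specimen_id in seen:
            logger.warning("duplicate specimen id %r written", cfg.specimen_id)
        seen.add(cfg.specimen_id)
        pts = cfg.points
        if cfg.scale_factor is not None:
            pts = pts / cfg.scale_factor
        out.append(f"LM={cfg.n_points}")
        for x, y in pts:
            out.append(f"{x:.17g} {y:.17g}")
        if cfg.species:
            out.append(f"COMMENT={cfg.species}")
        if cfg.scale_factor is not None:
            out.append(f"SCALE={cfg.scale_factor:.17g}")
        out.append(f"ID={cfg.specimen_id}")
    Path(path).write_text("\n".join(out) + "\n")


def read_coordinate_matrix(
    path,
    n_landmarks: int,
    roles=paper_roles,
    specimen_ids: Sequence[str] | None = None,
) -> list[LandmarkConfiguration]:
    """Read the "matrix" dialect: one specimen per row, ``x1 y1 ... xk yk``.

    This is the layout in which superimposed coordinates are typically
    deposited (e.g. tpsRelw aligned-specimen exports).
    """
    raw = np.loadtxt(path, dtype=float, ndmin=2)
    if raw.shape[1] != 2 * n_landmarks:
        raise TpsParseError(
            f"expected {2 * n_landmarks} columns for {n_landmarks} landmarks, "
            f"found {raw.shape[1]}"
        )
    rec_roles = roles(n_landmarks) if callable(roles) else tuple(roles)
    configs = []
    for r, row in enumerate(raw):
        sid = specimen_ids[r] if specimen_ids is not None else f"row_{r + 1}"
        configs.append(
            LandmarkConfiguration(
                specimen_id=sid,
                species="",
                points=row.reshape(n_landmarks, 2),
                roles=rec_roles,
            )
        )
    return configs


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------

_DEFAULT_COLUMN_MAP = {name: name for name in MEASUREMENT_TRAITS} | {
    "species": "species",
    "specimen_id": "specimen_id",
    "altitude": "altitude",
}


def read_measurements(
    path,
    column_map: Mapping[str, str] | None = None,
    sep: str = ",",
) -> list[MeasurementRecord]:
    """Read a delimited measurement table into records.

    ``column_map`` maps canonical field names (``body_weight`` ...) to the
    file's header names, accommodating arbitrary deposited layouts; header
    matching is case-insensitive. Unparseable numeric cells are flagged
    missing rather than raised.
    """
    cmap = dict(_DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep, dtype=str)
    lower = {c.lower(): c for c in df.columns}
    mandatory = list(MEASUREMENT_TRAITS) + ["species"]
    missing = [
        f for f in mandatory if cmap[f].lower() not in lower
    ]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")

    def col(field_name: str) -> str | None:
        c = cmap[field_name].lower()
        return lower.get(c)

    records = []
    for idx, row in df.iterrows():
        kwargs: dict = {}
        sid_col = col("specimen_id")
        kwargs["specimen_id"] = (
            str(row[sid_col]) if sid_col and pd.notna(row[sid_col]) else f"row_{idx + 1}"
        )
        kwargs["species"] = str(row[col("species")])
        for f in list(MEASUREMENT_TRAITS) + ["altitude"]:
            c = col(f)
            v = None
            if c is not None and pd.notna(row[c]):
                try:
                    v = float(row[c])
                    if math.isnan(v):
                        v = None
                except ValueError:
                    v = None  # flagged missing, not an error
            kwargs[f] = v
        records.append(MeasurementRecord(**kwargs))
    return records


def write_measurements(records: Sequence[MeasurementRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "species": r.species,
                **r.trait_values(),
                "altitude": r.altitude,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def measurements_frame(records: Sequence[MeasurementRecord]) -> pd.DataFrame:
    """Records as a DataFrame (NaN marks missing), indexed by specimen."""
    rows = {
        r.specimen_id: {
            "species": r.species,
            **{t: (np.nan if v is None else v) for t, v in r.trait_values().items()},
            "altitude": np.nan if r.altitude is None else r.altitude,
        }
        for r in records
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "specimen_id"
    return df


# ---------------------------------------------------------------------------
# trees and ranges
# ---------------------------------------------------------------------------


def read_newick(path_or_text, default_branch_length: float = 1.0) -> Phylogeny:
    """Read a rooted Newick tree from a path or a literal string."""
    text = str(path_or_text)
    if not text.strip().endswith(";"):
        text = Path(path_or_text).read_text()
    return Phylogeny.from_newick(text, default_branch_length=default_branch_length)


def write_newick(tree: Phylogeny, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_ranges(species_path, overlap_path) -> list[RangeRecord]:
    """Read the per-species range table and the long pairwise-overlap table.

    Missing pairs default to zero overlap (logged), the convention for
    ranges whose polygons do not intersect.
    """
    sp = pd.read_csv(species_path)
    need = {"species", "area", "alt_min", "alt_max"}
    if not need <= set(sp.columns):
        raise SchemaError(f"range table needs columns {sorted(need)}")
    ov = pd.read_csv(overlap_path)
    need_ov = {"species_a", "species_b", "overlap_area"}
    if not need_ov <= set(ov.columns):
        raise SchemaError(f"overlap table needs columns {sorted(need_ov)}")
    overlap: dict[str, dict[str, float]] = {s: {} for s in sp["species"]}
    for _, row in ov.iterrows():
        a, b, o = row["species_a"], row["species_b"], float(row["overlap_area"])
        overlap.setdefault(a, {})[b] = o
        overlap.setdefault(b, {})[a] = o
    records = []
    species = list(sp["species"])
    for _, row in sp.iterrows():
        s = row["species"]
        pairs = {}
        for other in species:
            if other == s:
                continue
            if other not in overlap.get(s, {}):
                logger.info("no overlap entry for (%s, %s); assuming 0", s, other)
            pairs[other] = overlap.get(s, {}).get(other, 0.0)
        records.append(
            RangeRecord(
                species=s,
                area=float(row["area"]),
                pairwise_overlap=pairs,
                alt_min=float(row["alt_min"]),
                alt_max=float(row["alt_max"]),
            )
        )
    return records


def write_ranges(records: Sequence[RangeRecord], species_path, overlap_path) -> None:
    sp_rows = [
        {
            "species": r.species,
            "area": r.area,
            "alt_min": r.alt_min,
            "alt_max": r.alt_max,
        }
        for r in records
    ]
    pd.DataFrame(sp_rows).to_csv(species_path, index=False)
    ov_rows = []
    done = set()
    for r in records:
        for other, o in r.pairwise_overlap.items():
            key = tuple(sorted((r.species, other)))
            if key in done:
                continue
            done.add(key)
            ov_rows.append({"species_a": key[0], "species_b": key[1], "overlap_area": o})
    pd.DataFrame(ov_rows).to_csv(overlap_path, index=False)
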