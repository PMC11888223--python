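"""Synthetic trichromatic cone mosaics and geometric queries on them.

A mosaic is a jittered hexagonal lattice of cone positions (arcmin,
origin at the patch centre) with one spectral class per cone: L, M, S,
or U (unclassified).  Parafoveal primate mosaics are close to hexagonal
packing, and the analyses built on top of these mosaics only need a
realistic local density and a controllable global L:M ratio, so the
lattice-plus-Gaussian-jitter model is deliberately simple.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError, cKDTree

from .exceptions import GeometryError, InvalidParameterError, MissingClassError

CONE_CLASSES = ("L", "M", "S", "U")


@dataclass
class ConeMosaic:
    """Cone positions (n, 2) in arcmin plus one spectral class per cone.

    ``patch_extent`` is the (width, height) of the classified patch in
    arcmin, centred on the origin.  ``eccentricity_deg`` and
    ``nominal_spacing`` are metadata carried through to output tables.
    """

    positions: np.ndarray
    classes: np.ndarray
    patch_extent: tuple[float, float]
    eccentricity_deg: float = float("nan")
    nominal_spacing: float = float("nan")
    _trees: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.classes = np.asarray(self.classes, dtype="U1")
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise InvalidParameterError("positions must have shape (n, 2)")
        if self.classes.shape[0] != self.positions.shape[0]:
            raise InvalidParameterError("one class per cone required")
        bad = set(np.unique(self.classes)) - set(CONE_CLASSES)
        if bad:
            raise InvalidParameterError(f"unknown cone classes: {sorted(bad)}")
        hw, hh = self.patch_extent[0] / 2, self.patch_extent[1] / 2
        x, y = self.positions.T
        if self.n and (np.abs(x).max() > hw + 1e-9 or np.abs(y).max() > hh + 1e-9):
            raise InvalidParameterError("cone positions outside patch_extent")

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.classes == c)) for c in CONE_CLASSES}

    def positions_of(self, cls: str) -> np.ndarray:
        return self.positions[self.classes == cls]

    @property
    def proportion_L(self) -> float:
        """Global #L / (#L + #M) over classified cones."""
        c = self.class_counts()
        if c["L"] + c["M"] == 0:
            raise MissingClassError("mosaic has no classified L or M cones")
        return c["L"] / (c["L"] + c["M"])

    def tree(self, cls: str | None = None) -> cKDTree:
        """KD-tree over all cones, or over one class (cached)."""
        key = cls or "*"
        if key not in self._trees:
            pts = self.positions if cls is None else self.positions_of(cls)
            if pts.shape[0] == 0:
                raise MissingClassError(f"mosaic has no {cls} cones")
            self._trees[key] = cKDTree(pts)
        return self._trees[key]


def _hex_lattice(n_points: int, spacing: float) -> np.ndarray:
    """The n_points hexagonal-lattice sites closest to the origin."""
    # generate a lattice block comfortably larger than needed, then trim
    half = int(np.ceil(np.sqrt(n_points / (np.sqrt(3) / 2)) / 2)) + 2
    rows = np.arange(-half, half + 1)
    cols = np.arange(-half, half + 1)
    cc, rr = np.meshgrid(cols, rows)
    x = (cc + 0.5 * (rr % 2)) * spacing
    y = rr * spacing * np.sqrt(3) / 2
    pts = np.column_stack([x.ravel(), y.ravel()])
    order = np.argsort(np.einsum("ij,ij->i", pts, pts), kind="stable")
    return pts[order[:n_points]]


def generate_mosaic(
    n_cones: int,
    spacing: float = 1.1,
    jitter_sd: float = 0.1,
    fraction_L_of_LM: float = 0.595,
    fraction_S: float = 0.05,
    seed: int | np.random.Generator = 0,
    fraction_unclassified: float = 0.0,
    clumping: int = 0,
    eccentricity_deg: float = float("nan"),
) -> ConeMosaic:
    """Jittered hexagonal mosaic with i.i.d. spectral-class assignment.

    ``fraction_L_of_LM`` is the probability that a non-S classified cone
    is L, so the expected global proportion L equals it regardless of
    ``fraction_S``.  ``fraction_unclassified`` marks that fraction of
    cones U before the S/L/M split.  Identical seeds give identical
    mosaics.
    """
    if n_cones < 1:
        raise InvalidParameterError("n_cones must be >= 1")
    if spacing <= 0:
        raise InvalidParameterError("spacing must be > 0")
    if jitter_sd < 0:
        raise InvalidParameterError("jitter_sd must be >= 0")
    for name, f in (
        ("fraction_L_of_LM", fraction_L_of_LM),
        ("fraction_S", fraction_S),
        ("fraction_unclassified", fraction_unclassified),
    ):
        if not 0 <= f <= 1:
            raise InvalidParameterError(f"{name} must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    pos = _hex_lattice(n_cones, spacing)
    if jitter_sd > 0:
        pos = pos + rng.normal(0.0, jitter_sd, size=pos.shape)
    w = rng.random(n_cones)
    u = rng.random(n_cones)
    v = rng.random(n_cones)
    classes = np.where(
        w < fraction_unclassified,
        "U",
        np.where(u < fraction_S, "S", np.where(v < fraction_L_of_LM, "L", "M")),
    )
    if clumping > 0:
        # optional spatial correlation: each round, every L/M cone copies
        # the class of a random near neighbour, producing same-class
        # pockets while leaving the expected global ratio unchanged
        tree = cKDTree(pos)
        lm = np.flatnonzero((classes == "L") | (classes == "M"))
        for _ in range(clumping):
            _, nbrs = tree.query(pos[lm], k=7)
            pick = nbrs[np.arange(lm.size), rng.integers(1, 7, size=lm.size)]
            ok = (classes[pick] == "L") | (classes[pick] == "M")
            classes[lm[ok]] = classes[pick[ok]]

    hw = np.abs(pos[:, 0]).max() + spacing
    hh = np.abs(pos[:, 1]).max() + spacing
    return ConeMosaic(
        positions=pos,
        classes=classes,
        patch_extent=(2 * hw, 2 * hh),
        eccentricity_deg=eccentricity_deg,
        nominal_spacing=spacing,
    )


def cone_spacing(mosaic: ConeMosaic) -> float:
    """Mean edge length of the Delaunay triangulation of cone positions."""
    if mosaic.n < 3:
        raise GeometryError("cone spacing needs at least 3 cones")
    try:
        tri = Delaunay(mosaic.positions)
    except QhullError as err:
        raise GeometryError(f"degenerate cone geometry: {err}") from err
    s = tri.simplices
    edges = np.unique(
        np.sort(np.concatenate([s[:, [0, 1]], s[:, [1, 2]], s[:, [0, 2]]]), axis=1),
        axis=0,
    )
    d = mosaic.positions[edges[:, 0]] - mosaic.positions[edges[:, 1]]
    return float(np.hypot(d[:, 0], d[:, 1]).mean())


def nearest_s_distance(
    mosaic: ConeMosaic,
    point: tuple[float, float],
    spacing: float | None = None,
) -> float:
    """Distance from ``point`` to the nearest S cone, in cone-spacing units.

    ``spacing`` (arcmin) may be passed to avoid re-triangulating when the
    same mosaic is queried many times.
    """
    s_pts = mosaic.positions_of("S")
    if s_pts.shape[0] == 0:
        raise MissingClassError("mosaic contains no S cones")
    d = float(mosaic.tree("S").query(np.asarray(point, dtype=float))[0])
    if spacing is None:
        spacing = cone_spacing(mosaic)
    return d / spacing


# ---------------------------------------------------------------------------
# table I/O: one row per cone, lossless round-trip including metadata
# ---------------------------------------------------------------------------

def write_mosaic(mosaic: ConeMosaic, path, extra_header: dict | None = None) -> None:
    meta = {
        "patch_extent_x_arcmin": repr(float(mosaic.patch_extent[0])),
        "patch_extent_y_arcmin": repr(float(mosaic.patch_extent[1])),
        "eccentricity_deg": repr(float(mosaic.eccentricity_deg)),
        "nominal_spacing_arcmin": repr(float(mosaic.nominal_spacing)),
    }
    meta.update(extra_header or {})
    df = pd.DataFrame(
        {
            "x_arcmin": mosaic.positions[:, 0],
            "y_arcmin": mosaic.positions[:, 1],
            "class": mosaic.classes,
        }
    )
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k} = {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_mosaic(path) -> ConeMosaic:
    meta: dict[str, str] = {}
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                k, _, v = line[1:].partition("=")
                meta[k.strip()] = v.strip()
            else:
                lines.append(line)
    df = pd.read_csv(
        io.StringIO("".join(lines)), sep="\t", dtype={"class": str},
        float_precision="round_trip",
    )
    return ConeMosaic(
        positions=df[["x_arcmin", "y_arcmin"]].to_numpy(),
        classes=df["class"].to_numpy(),
        patch_extent=(
            float(meta["patch_extent_x_arcmin"]),
            float(meta["patch_extent_y_arcmin"]),
        ),
        eccentricity_deg=float(meta.get("eccentricity_deg", "nan")),
        nominal_spacing=float(meta.get("nominal_spacing_arcmin", "nan")),
    )
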