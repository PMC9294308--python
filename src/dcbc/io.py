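"""File formats, configuration, and the simulation-validation workflow.

Formats
-------
* Surfaces: GIFTI ``.surf.gii`` (POINTSET + TRIANGLE arrays).
* Parcellations: GIFTI ``.label.gii`` (label table, key 0 = unassigned) or a
  one-column integer TSV.
* Functional profiles: GIFTI ``.func.gii`` (one data array per condition;
  several single-array files may be concatenated) or a vertices x conditions
  TSV.  Rows containing non-finite values are masked invalid.
* Distance matrices: HDF5 with triplet datasets ``i``, ``j``, ``d`` and
  attributes ``cutoff_mm`` / ``n_vertices``; or a 3-column TSV for small
  fixtures (attributes in ``#``-comment header lines).
* Reports: TSV with the configuration and seed embedded as ``#`` header
  lines, so every result file records how it was produced.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .criteria import (
    BinSpec,
    FunctionalProfiles,
    compute_dcbc,
    compute_homogeneity,
    compute_silhouette,
    unbinned_acd,
)
from .exceptions import FormatError, ParameterError
from .mesh import SparseDistanceMatrix, SurfaceMesh, geodesic_distances
from .parcellation import (
    ICOSAHEDRAL_PARCEL_COUNTS,
    Parcellation,
    parcel_adjacency,
    random_parcellation_set,
)
from .synthetic import (
    calibrate_smoothing,
    distance_matched_generator,
    make_smooth_random_map,
)
from dataclasses import replace

logger = logging.getLogger("dcbc")

__all__ = [
    "EvaluationConfig",
    "read_surface",
    "write_surface",
    "read_parcellation",
    "write_parcellation",
    "read_profiles",
    "write_profiles",
    "read_distances",
    "write_distances",
    "write_report",
    "run_validation_suite",
]


@dataclass(frozen=True)
class EvaluationConfig:
    """Defaults of the evaluation workflow.

    ``max_dist_mm`` bounds the pair distances entering the criteria and must
    not exceed ``distance_cutoff_mm``, the radius up to which geodesic
    distances are computed and stored.
    """

    bin_width_mm: float = 1.0
    max_dist_mm: float = 35.0
    distance_cutoff_mm: float = 50.0
    hemisphere_mode: str = "separate-then-average"  # or "single"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_width_mm <= 0:
            raise ParameterError("bin_width_mm must be positive")
        if self.max_dist_mm > self.distance_cutoff_mm:
            raise ParameterError("max_dist_mm must not exceed distance_cutoff_mm")
        if self.hemisphere_mode not in ("separate-then-average", "single"):
            raise ParameterError(f"unknown hemisphere_mode {self.hemisphere_mode!r}")

    @property
    def binspec(self) -> BinSpec:
        return BinSpec(bin_width_mm=self.bin_width_mm, max_dist_mm=self.max_dist_mm)


# ---------------------------------------------------------------------------
# GIFTI helpers
# ---------------------------------------------------------------------------

def _load_gifti(path: Path):
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of classes on bad files
        raise FormatError(f"cannot read GIFTI file {path}: {exc}") from exc
    import nibabel.gifti as gifti

    if not isinstance(img, gifti.GiftiImage):
        raise FormatError(f"{path} is not a GIFTI file")
    return img


def read_surface(path: str | Path) -> SurfaceMesh:
    """Read a triangulated surface from a GIFTI ``.surf.gii`` file."""
    from nibabel.nifti1 import intent_codes

    img = _load_gifti(Path(path))
    points = tris = None
    for arr in img.darrays:
        if arr.intent == intent_codes["NIFTI_INTENT_POINTSET"]:
            points = np.asarray(arr.data, dtype=np.float64)
        elif arr.intent == intent_codes["NIFTI_INTENT_TRIANGLE"]:
            tris = np.asarray(arr.data, dtype=np.int64)
    if points is None or tris is None:
        raise FormatError(f"{path} lacks POINTSET and/or TRIANGLE arrays")
    return SurfaceMesh(vertices=points, faces=tris)


def write_surface(mesh: SurfaceMesh, path: str | Path) -> None:
    import nibabel as nib
    from nibabel import gifti
    from nibabel.nifti1 import intent_codes

    img = gifti.GiftiImage(
        darrays=[
            gifti.GiftiDataArray(
                mesh.vertices.astype(np.float32),
                intent=intent_codes["NIFTI_INTENT_POINTSET"],
            ),
            gifti.GiftiDataArray(
                mesh.faces.astype(np.int32),
                intent=intent_codes["NIFTI_INTENT_TRIANGLE"],
            ),
        ]
    )
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Parcellations
# ---------------------------------------------------------------------------

def read_parcellation(
    path: str | Path, n_vertices: int | None = None
) -> Parcellation:
    """Read labels from ``.label.gii`` or a one-column integer TSV."""
    path = Path(path)
    if path.suffix == ".gii":
        img = _load_gifti(path)
        if not img.darrays:
            raise FormatError(f"{path} contains no data arrays")
        data = np.asarray(img.darrays[0].data)
        if not np.issubdtype(data.dtype, np.integer):
            if not np.array_equal(data, np.round(data)):
                raise FormatError(f"{path}: labels are not integers")
        labels = data.astype(np.int64)
        name = path.stem
    else:
        try:
            table = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
            col = table.iloc[:, 0].to_numpy(dtype=float)
        except Exception as exc:
            raise FormatError(f"cannot parse {path} as a label table: {exc}") from exc
        if table.shape[1] != 1:
            raise FormatError(f"{path}: expected one label column, got {table.shape[1]}")
        if not np.array_equal(col, np.round(col)):
            raise FormatError(f"{path}: labels are not integers")
        labels = col.astype(np.int64)
        name = path.stem
    if n_vertices is not None and len(labels) != n_vertices:
        raise FormatError(
            f"{path}: {len(labels)} labels but the surface has {n_vertices} vertices"
        )
    return Parcellation(labels=labels, name=name)


def write_parcellation(parcellation: Parcellation, path: str | Path) -> None:
    """Write ``.label.gii`` (with a generated label table) or TSV."""
    path = Path(path)
    if path.suffix == ".gii":
        import nibabel as nib
        from nibabel import gifti
        from nibabel.nifti1 import intent_codes

        table = gifti.GiftiLabelTable()
        rng = np.random.default_rng(0)  # colors are cosmetic but reproducible
        wall = gifti.GiftiLabel(key=0, red=0, green=0, blue=0, alpha=0)
        wall.label = "???"
        table.labels.append(wall)
        for k in parcellation.parcel_ids:
            r, g, b = rng.uniform(0.2, 1.0, 3)
            lab = gifti.GiftiLabel(key=int(k), red=r, green=g, blue=b, alpha=1.0)
            lab.label = f"parcel-{int(k)}"
            table.labels.append(lab)
        img = gifti.GiftiImage(
            darrays=[
                gifti.GiftiDataArray(
                    parcellation.labels.astype(np.int32),
                    intent=intent_codes["NIFTI_INTENT_LABEL"],
                    datatype="NIFTI_TYPE_INT32",
                )
            ],
            labeltable=table,
        )
        nib.save(img, str(path))
    else:
        np.savetxt(path, parcellation.labels, fmt="%d", delimiter="\t")


# ---------------------------------------------------------------------------
# Functional profiles
# ---------------------------------------------------------------------------

def read_profiles(paths: str | Path | list[str | Path]) -> FunctionalProfiles:
    """Read a vertices x conditions matrix from GIFTI metric file(s) or TSV.

    Multiple GIFTI files are concatenated along conditions and must agree on
    vertex count.  Rows with any non-finite value are masked invalid.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    columns: list[np.ndarray] = []
    n_vertices = None
    for p in paths:
        p = Path(p)
        if p.suffix == ".gii":
            img = _load_gifti(p)
            if not img.darrays:
                raise FormatError(f"{p} contains no data arrays")
            arrays = [np.asarray(a.data, dtype=np.float64).ravel() for a in img.darrays]
        else:
            try:
                table = pd.read_csv(p, sep=r"\s+", header=None, comment="#")
                arrays = [
                    table.iloc[:, c].to_numpy(dtype=np.float64)
                    for c in range(table.shape[1])
                ]
            except Exception as exc:
                raise FormatError(f"cannot parse {p} as a profile matrix: {exc}") from exc
        for a in arrays:
            if n_vertices is None:
                n_vertices = len(a)
            elif len(a) != n_vertices:
                raise FormatError("vertex counts differ across profile files/arrays")
            columns.append(a)
    if len(columns) < 2:
        raise FormatError(f"need >= 2 conditions, got {len(columns)}")
    return FunctionalProfiles(np.column_stack(columns))


def write_profiles(profiles: FunctionalProfiles, path: str | Path) -> None:
    """Write as ``.func.gii`` (one array per condition) or TSV matrix."""
    path = Path(path)
    values = profiles.values.copy()
    values[~profiles.valid_mask] = np.nan
    if path.suffix == ".gii":
        import nibabel as nib
        from nibabel import gifti
        from nibabel.nifti1 import intent_codes

        img = gifti.GiftiImage(
            darrays=[
                gifti.GiftiDataArray(
                    values[:, c].astype(np.float32),
                    intent=intent_codes["NIFTI_INTENT_NONE"],
                )
                for c in range(values.shape[1])
            ]
        )
        nib.save(img, str(path))
    else:
        np.savetxt(path, values, fmt="%.10g", delimiter="\t")


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

def write_distances(
    dist: SparseDistanceMatrix, path: str | Path, config: EvaluationConfig | None = None
) -> None:
    """HDF5 triplet container (``.h5``/``.hdf5``) or 3-column TSV."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("i", data=dist.i, compression="gzip")
            f.create_dataset("j", data=dist.j, compression="gzip")
            f.create_dataset("d", data=dist.d, compression="gzip")
            f.attrs["cutoff_mm"] = dist.cutoff_mm
            f.attrs["n_vertices"] = dist.n_vertices
            if config is not None:
                for k, v in asdict(config).items():
                    f.attrs[f"config_{k}"] = v
    else:
        header = (
            f"# cutoff_mm = {dist.cutoff_mm}\n# n_vertices = {dist.n_vertices}\n"
        )
        if config is not None:
            header += "".join(f"# config_{k} = {v}\n" for k, v in asdict(config).items())
        with open(path, "w") as f:
            f.write(header)
            np.savetxt(f, np.column_stack([dist.i, dist.j, dist.d]), fmt="%d\t%d\t%.8f")


def read_distances(path: str | Path) -> SparseDistanceMatrix:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        try:
            with h5py.File(path, "r") as f:
                return SparseDistanceMatrix(
                    i=f["i"][:], j=f["j"][:], d=f["d"][:],
                    n_vertices=int(f.attrs["n_vertices"]),
                    cutoff_mm=float(f.attrs["cutoff_mm"]),
                )
        except (KeyError, OSError) as exc:
            raise FormatError(f"cannot read distance container {path}: {exc}") from exc
    cutoff = n_vertices = None
    with open(path) as f:
        for line in f:
            if not line.startswith("#"):
                break
            if "cutoff_mm" in line:
                cutoff = float(line.split("=")[1])
            elif "n_vertices" in line:
                n_vertices = int(line.split("=")[1])
    if cutoff is None or n_vertices is None:
        raise FormatError(f"{path}: missing cutoff_mm / n_vertices header lines")
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.size == 0:
        data = data.reshape(0, 3)
    if data.shape[1] != 3:
        raise FormatError(f"{path}: expected 3 columns (i, j, d)")
    return SparseDistanceMatrix(
        i=data[:, 0].astype(np.int64), j=data[:, 1].astype(np.int64),
        d=data[:, 2], n_vertices=n_vertices, cutoff_mm=cutoff,
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(
    table: pd.DataFrame, path: str | Path, config: EvaluationConfig | None = None,
    extra: dict | None = None,
) -> None:
    """TSV report with the configuration embedded as ``#`` header lines."""
    meta = dict(asdict(config)) if config is not None else {}
    if extra:
        meta.update(extra)
    with open(path, "w") as f:
        for k, v in meta.items():
            f.write(f"# {k} = {v}\n")
        table.to_csv(f, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# Simulation-validation workflow
# ---------------------------------------------------------------------------

def run_validation_suite(
    config: EvaluationConfig,
    mesh: SurfaceMesh,
    *,
    dist: SparseDistanceMatrix | None = None,
    n_maps: int = 20,
    parcel_counts: tuple[int, ...] = ICOSAHEDRAL_PARCEL_COUNTS,
    target_half_distance_mm: float = 15.0,
    generator: str = "distance-matched",
    compute_baselines: bool = True,
) -> pd.DataFrame:
    """Evaluate all criteria on random smooth maps x random parcellations.

    For every parcel count and every simulated map, one randomly rotated
    icosahedral parcellation is drawn and evaluated with Homogeneity,
    Silhouette, un-binned ACD and the weighted / un-weighted DCBC at the
    configured bin width.  All randomness derives from ``config.seed``.
    ``generator`` selects the random-map model: ``"distance-matched"``
    (Gaussian process with correlation an explicit function of the measured
    geodesic distance; the default, see :mod:`dcbc.synthetic`) or
    ``"neighbor-smoothing"`` (iterative diffusion of white noise).
    Returns one row per (parcel count, map).
    """
    if dist is None:
        dist = geodesic_distances(mesh, config.distance_cutoff_mm)
    ss = np.random.SeedSequence(config.seed)
    map_seeds, parc_seeds = ss.spawn(2)
    map_seed_ints = map_seeds.generate_state(n_maps) % (2**31)
    parc_seed_ints = parc_seeds.generate_state(n_maps * len(parcel_counts)) % (2**31)

    if generator == "distance-matched":
        gen = distance_matched_generator(dist, target_half_distance_mm)
        logger.info(
            "distance-matched generator: length scale %.2f mm", gen.length_scale_mm
        )
        maps = [gen.sample(int(s)) for s in map_seed_ints]
    elif generator == "neighbor-smoothing":
        cal = calibrate_smoothing(
            mesh, dist, target_half_distance_mm, seed=config.seed,
            binspec=BinSpec(1.0, config.max_dist_mm),
        )
        logger.info(
            "calibrated smoothing: %d iterations, half-distance %.1f mm",
            cal.spec.n_iterations, cal.half_distance_mm,
        )
        maps = [
            make_smooth_random_map(mesh, replace(cal.spec, seed=int(s)))
            for s in map_seed_ints
        ]
    else:
        raise ParameterError(f"unknown generator {generator!r}")
    binspec = config.binspec
    rows = []
    k = 0
    for n_parcels in parcel_counts:
        for m, profiles in enumerate(maps):
            parc = random_parcellation_set(
                mesh, n_parcels, 1, int(parc_seed_ints[k])
            )[0]
            k += 1
            res = compute_dcbc(profiles, parc, dist, binspec)
            logger.info(
                "parcels=%d map=%d: %d/%d bins used, excluded=%s",
                n_parcels, m, res.n_bins_used, binspec.n_bins,
                res.excluded_bins.tolist(),
            )
            row = {
                "n_parcels": n_parcels,
                "map_index": m,
                "map_seed": int(map_seed_ints[m]),
                "dcbc_weighted": res.dcbc,
                "dcbc_unweighted": res.dcbc_unweighted,
                "acd_unbinned": unbinned_acd(profiles, parc, dist, config.max_dist_mm),
                "n_bins_used": res.n_bins_used,
                "bin_width_mm": config.bin_width_mm,
            }
            if compute_baselines:
                adj = parcel_adjacency(parc, mesh)
                row["homogeneity"] = compute_homogeneity(profiles, parc)
                row["silhouette"] = compute_silhouette(profiles, parc, adj)[1]
            rows.append(row)
    return pd.DataFrame(rows)
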