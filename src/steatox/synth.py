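"""Synthetic data generators with known ground truth.

Every downstream stage of the pipeline — segmentation, endpoint
normalization, dose-response fitting, benchmark-concentration modeling,
and IVIVE — is exercised against data produced here, with the truth
recorded so recovery can be checked exactly.

Four generators:

* :func:`generate_image_scene` — a 4-channel 16-bit fluorescence field
  (nuclei/Hoechst, lipid/Bodipy, mitochondria/Mitotracker, oxidative
  stress/CellROX) with two cell populations (small hepatocyte-like and
  large cholangiocyte-like cells), per-cell lipid droplets, and
  apoptotic nuclei rendered as 2-5 fragments. Nuclei are discs with
  Gaussian edge blur; no optics/PSF modeling is attempted.
* :func:`generate_plate_dataset` — per-well endpoint fold changes for a
  dose series (default 3 independent experiments x 6 technical
  replicates per concentration on 8-point series), drawn as
  log-logistic truth value x a multiplicative log-normal plate effect
  + Gaussian well noise, with vehicle wells on every plate.
* :func:`generate_single_cell_matrix` — a per-cell feature matrix with a
  cytoplasm-area column spanning the 5000 px^2 hepatocyte /
  cholangiocyte gate, optional injected constant and missing-value
  columns, and a "protected subpopulation" in which large-droplet cells
  receive lower oxidative-stress intensity.
* :func:`generate_pk_truth_set` — chemicals with known toxicokinetic
  parameters and a simulated in vivo Css derived from the steady-state
  model and perturbed by a stated log-normal error.

All randomness flows through one seeded numpy Generator passed
explicitly; fixed seeds reproduce outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .endpoints import log_logistic
from .ivive import ChemicalPK, PhysiologyParams, calc_css

__all__ = [
    "PlacementError",
    "ImageSceneSpec",
    "ImageScene",
    "CurveParams",
    "ChemicalProfile",
    "SingleCellSpec",
    "PKTruthChemical",
    "generate_image_scene",
    "generate_plate_dataset",
    "generate_single_cell_matrix",
    "generate_nucleus_features",
    "generate_pk_truth_set",
]


class PlacementError(RuntimeError):
    """Raised when the requested cell count cannot be placed on the canvas."""


# ---------------------------------------------------------------------------
# image scenes


@dataclass(frozen=True)
class ImageSceneSpec:
    """Parameters of one synthetic 4-channel field of view.

    Intensities are 16-bit counts; geometry is in raw image pixels.
    ``nucleus_diameter_range`` bounds the uniform draw of nucleus
    diameters; hepatocyte/cholangiocyte cytoplasm radii are derived from
    the target cytoplasm areas (~3000 and ~8000 px^2).
    """

    width: int = 512
    height: int = 512
    n_hepatocytes: int = 12
    n_cholangiocytes: int = 0
    nucleus_diameter_range: tuple[float, float] = (16.0, 24.0)
    droplets_per_cell_mean: float = 4.0
    droplet_radius_range: tuple[float, float] = (2.0, 4.0)
    channel_gains: dict = field(default_factory=lambda: {
        "nuclei": 20000.0, "lipid": 15000.0, "mito": 12000.0,
        "oxstress": 8000.0})
    cell_background: dict = field(default_factory=lambda: {
        "lipid": 800.0, "mito": 0.0, "oxstress": 0.0})
    noise_sd: float = 0.0
    apoptotic_fraction: float = 0.0
    edge_blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hepatocytes < 0 or self.n_cholangiocytes < 0:
            raise ValueError("cell counts must be >= 0")
        lo, hi = self.nucleus_diameter_range
        if not 1 <= lo <= hi <= min(self.width, self.height):
            raise ValueError("nucleus diameters must lie in "
                             "[1, min(width, height)]")
        if not 0.0 <= self.apoptotic_fraction <= 1.0:
            raise ValueError("apoptotic_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ImageScene:
    """A generated stack plus its ground truth.

    ``channels`` maps channel name to a 2-D uint16 raster. The truth
    label rasters assign one label per cell (an apoptotic nucleus's
    fragments share their cell's label). ``truth`` has one row per cell:
    cell_id, cell_type, centroid, nucleus diameter, droplet count,
    apoptotic flag.
    """

    channels: dict
    nucleus_truth_labels: np.ndarray
    cell_truth_labels: np.ndarray
    truth: pd.DataFrame

    CHANNEL_ORDER = ("nuclei", "lipid", "mito", "oxstress")

    def stack(self) -> np.ndarray:
        """Channels as one (4, H, W) uint16 array in canonical order."""
        return np.stack([self.channels[k] for k in self.CHANNEL_ORDER])

    def write_tiff(self, path) -> None:
        """Write the stack as a multi-page 16-bit TIFF (one page/channel)."""
        import tifffile
        tifffile.imwrite(path, self.stack())


def read_stack_tiff(path) -> dict:
    """Read a multi-page 16-bit TIFF back into named channel rasters."""
    import tifffile
    arr = tifffile.imread(path)
    if arr.ndim != 3 or arr.shape[0] != len(ImageScene.CHANNEL_ORDER):
        raise ValueError("expected a 4-page stack (nuclei/lipid/mito/oxstress)")
    return dict(zip(ImageScene.CHANNEL_ORDER, arr))


def _disc_mask(shape, cy, cx, r):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


def _place_centers(rng, n, shape, radii, margin=8.0, max_tries=4000):
    """Rejection-sample non-overlapping centers; raise PlacementError."""
    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    for r in radii:
        for _ in range(max_tries):
            cy = rng.uniform(r + 2, shape[0] - r - 2)
            cx = rng.uniform(r + 2, shape[1] - r - 2)
            ok = all((cy - py) ** 2 + (cx - px) ** 2
                     >= (r + pr + margin) ** 2
                     for (py, px), pr in zip(centers, placed_r))
            if ok:
                centers.append((cy, cx))
                placed_r.append(r)
                break
        else:
            raise PlacementError(
                f"could not place {n} cells on a {shape[1]}x{shape[0]} "
                "canvas without overlap")
    return centers


def generate_image_scene(spec: ImageSceneSpec) -> ImageScene:
    """Render one 4-channel field with per-cell ground truth.

    Cells are placed by rejection sampling so cytoplasm discs do not
    overlap. Apoptotic nuclei (Bernoulli per cell at
    ``spec.apoptotic_fraction``) are rendered as 2-5 disc fragments
    scattered inside the nucleus footprint. Channels receive Gaussian
    edge blur and optional Gaussian read noise, then clip to uint16.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    n_total = spec.n_hepatocytes + spec.n_cholangiocytes
    types = (["hepatocyte"] * spec.n_hepatocytes
             + ["cholangiocyte"] * spec.n_cholangiocytes)
    # cytoplasm radii from target areas: hepatocyte ~3000, cholangiocyte ~8000
    cyto_r = {"hepatocyte": np.sqrt(3000 / np.pi),
              "cholangiocyte": np.sqrt(8000 / np.pi)}
    radii = [cyto_r[t] for t in types]
    centers = _place_centers(rng, n_total, (h, w), radii) if n_total else []

    chan = {k: np.zeros((h, w), dtype=float)
            for k in ("nuclei", "lipid", "mito", "oxstress")}
    nuc_labels = np.zeros((h, w), dtype=np.int32)
    cell_labels = np.zeros((h, w), dtype=np.int32)
    rows = []

    for i, ((cy, cx), ctype) in enumerate(zip(centers, types), start=1):
        d = rng.uniform(*spec.nucleus_diameter_range)
        r_nuc = d / 2.0
        r_cell = cyto_r[ctype]
        apoptotic = bool(rng.random() < spec.apoptotic_fraction)

        cell_mask = _disc_mask((h, w), cy, cx, r_cell)
        cell_labels[cell_mask] = i
        chan["mito"][cell_mask] = spec.channel_gains["mito"]
        chan["oxstress"][cell_mask] = spec.channel_gains["oxstress"]
        chan["lipid"][cell_mask] = spec.cell_background["lipid"]

        if apoptotic:
            # fragments on a ring inside the nucleus footprint, angularly
            # spaced so they stay disconnected after edge blur
            n_frag = int(rng.integers(2, 6))
            frag_r = max(r_nuc / 3.5, 1.5)
            ring = r_nuc * 0.65
            base_ang = rng.uniform(0, 2 * np.pi)
            for k in range(n_frag):
                ang = base_ang + 2 * np.pi * k / n_frag \
                    + rng.uniform(-0.15, 0.15)
                fy, fx = cy + ring * np.sin(ang), cx + ring * np.cos(ang)
                m = _disc_mask((h, w), fy, fx, frag_r)
                chan["nuclei"][m] = spec.channel_gains["nuclei"]
                nuc_labels[m] = i
        else:
            m = _disc_mask((h, w), cy, cx, r_nuc)
            chan["nuclei"][m] = spec.channel_gains["nuclei"]
            nuc_labels[m] = i

        n_drop = int(rng.poisson(spec.droplets_per_cell_mean))
        placed = 0
        drop_centers: list[tuple[float, float, float]] = []
        tries = 0
        while placed < n_drop and tries < 500:
            tries += 1
            dr = rng.uniform(*spec.droplet_radius_range)
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(r_nuc + dr + 1, r_cell - dr - 1) \
                if r_cell - dr - 1 > r_nuc + dr + 1 else None
            if rad is None:
                break
            dy, dx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            if all((dy - py) ** 2 + (dx - px) ** 2 >= (dr + pr + 2) ** 2
                   for py, px, pr in drop_centers):
                chan["lipid"][_disc_mask((h, w), dy, dx, dr)] = \
                    spec.channel_gains["lipid"]
                drop_centers.append((dy, dx, dr))
                placed += 1

        rows.append({"cell_id": i, "cell_type": ctype, "centroid_y": cy,
                     "centroid_x": cx, "nucleus_diameter": d,
                     "droplet_count": placed, "apoptotic": apoptotic})

    out = {}
    for name, img in chan.items():
        if spec.edge_blur_sigma > 0:
            img = gaussian_filter(img, spec.edge_blur_sigma)
        if spec.noise_sd > 0:
            img = img + rng.normal(0, spec.noise_sd, size=img.shape)
        out[name] = np.clip(img, 0, 65535).astype(np.uint16)

    truth = pd.DataFrame(rows, columns=["cell_id", "cell_type", "centroid_y",
                                        "centroid_x", "nucleus_diameter",
                                        "droplet_count", "apoptotic"])
    return ImageScene(out, nuc_labels, cell_labels, truth)


# ---------------------------------------------------------------------------
# plate datasets


@dataclass(frozen=True)
class CurveParams:
    """Log-logistic truth parameters (slope b, asymptotes c <= d, inflection e)."""

    b: float
    c: float
    d: float
    e: float

    def __post_init__(self) -> None:
        if self.e <= 0:
            raise ValueError("inflection e must be > 0")
        if self.c > self.d:
            raise ValueError("require c <= d")

    def value(self, conc):
        return log_logistic(conc, self.b, self.c, self.d, self.e)


@dataclass(frozen=True)
class ChemicalProfile:
    """True dose-response behaviour of one chemical across endpoints.

    ``endpoints`` maps endpoint name to its truth curve; the curve's
    zero-concentration limit should be 1 (vehicle fold change).
    """

    name: str
    endpoints: dict
    tested_concentrations: tuple

    def __post_init__(self) -> None:
        c = np.asarray(self.tested_concentrations, dtype=float)
        if c.size < 2 or np.any(np.diff(c) <= 0):
            raise ValueError("tested concentrations must be strictly "
                             "increasing with >= 2 anchor doses")
        if np.any(c <= 0):
            raise ValueError("tested concentrations must be > 0")


def generate_plate_dataset(
    profiles: list[ChemicalProfile],
    replicates: int = 6,
    experiments: int = 3,
    noise_sd: float = 0.05,
    plate_effect_sd: float = 0.1,
    n_vehicle: int = 6,
    seed: int | np.random.Generator | None = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate per-well endpoint fold changes for a plate study.

    One plate per chemical x experiment carries the full dose series
    (``replicates`` technical replicates per concentration) plus
    ``n_vehicle`` vehicle wells at concentration 0. The raw well value is
    truth-curve value x a log-normal plate factor (sigma
    ``plate_effect_sd`` on the log scale) + N(0, ``noise_sd``), clipped
    at 0. Per-plate vehicle normalization downstream cancels the plate
    factor.

    Returns the well table (one row per well, one column per endpoint)
    and a truth dict mapping (chemical, endpoint) -> CurveParams.
    """
    if not profiles:
        raise ValueError("profile list must not be empty")
    if replicates < 2:
        raise ValueError("need >= 2 replicates")
    for p in profiles:
        if len(p.tested_concentrations) < 4:
            raise ValueError(f"{p.name}: need >= 4 concentrations")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    rows = []
    truth: dict = {}
    for prof in profiles:
        for ep, curve in prof.endpoints.items():
            truth[(prof.name, ep)] = curve
        for exp in range(1, experiments + 1):
            plate_id = f"{prof.name}_exp{exp}"
            factor = float(np.exp(rng.normal(0.0, plate_effect_sd)))
            concs = [0.0] * n_vehicle + [
                c for c in prof.tested_concentrations
                for _ in range(replicates)]
            for well_i, conc in enumerate(concs):
                row = {"plate_id": plate_id, "experiment": exp,
                       "chemical": prof.name, "concentration": conc,
                       "is_vehicle": conc == 0.0, "well": well_i}
                for ep, curve in prof.endpoints.items():
                    v = float(curve.value(conc)) * factor
                    if noise_sd > 0:
                        v += rng.normal(0.0, noise_sd)
                    row[ep] = max(v, 0.0)
                rows.append(row)
    return pd.DataFrame(rows), truth


def normalize_plate_wells(wells: pd.DataFrame,
                          endpoint_cols: list[str] | None = None
                          ) -> pd.DataFrame:
    """Per-plate vehicle normalization of a generated well table.

    Divides each endpoint column by the plate's vehicle-well mean,
    returning fold changes with vehicle mean 1 per plate — the same
    normalization the endpoint pipeline applies to raw quantifications.
    """
    if endpoint_cols is None:
        meta = {"plate_id", "experiment", "chemical", "concentration",
                "is_vehicle", "well"}
        endpoint_cols = [c for c in wells.columns if c not in meta]
    out = wells.copy()
    for plate, grp in wells.groupby("plate_id"):
        veh = grp[grp["is_vehicle"]]
        if veh.empty:
            raise ValueError(f"plate {plate!r} has no vehicle wells")
        for col in endpoint_cols:
            vmean = veh[col].mean()
            if vmean == 0:
                raise ValueError(f"plate {plate!r}: vehicle mean of {col} is 0")
            out.loc[grp.index, col] = grp[col] / vmean
    return out


# ---------------------------------------------------------------------------
# single-cell matrices


@dataclass(frozen=True)
class SingleCellSpec:
    """Statistical shape of the synthetic per-cell feature matrix.

    Cytoplasm areas are Gaussian per cell type (means straddling the
    5000 px^2 gate); ``oxstress_droplet_slope`` < 0 creates the
    "protected subpopulation" in which cells with larger lipid droplets
    show lower oxidative-stress intensity. ``n_constant_columns`` and
    ``n_nan_columns`` inject pathological columns for cleaning tests.
    """

    hepatocyte_fraction: float = 0.7
    hepatocyte_area: tuple[float, float] = (3000.0, 700.0)   # mean, sd px^2
    cholangiocyte_area: tuple[float, float] = (8000.0, 1200.0)
    droplet_count_mean: float = 4.0
    droplet_size: tuple[float, float] = (60.0, 20.0)          # mean, sd px^2
    mito_intensity: tuple[float, float] = (1000.0, 200.0)
    oxstress_intensity: tuple[float, float] = (500.0, 100.0)
    oxstress_droplet_slope: float = -2.0   # AU per px^2 of droplet size
    n_noise_features: int = 48
    n_constant_columns: int = 0
    n_nan_columns: int = 0
    nan_fraction: float = 0.2


def generate_single_cell_matrix(
    n_cells: int,
    spec: SingleCellSpec | None = None,
    seed: int | np.random.Generator | None = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell feature matrix plus a truth table of cell types.

    The matrix carries the measured feature families (size/shape,
    intensity, texture — ~60 columns at desk scale rather than the full
    800+) with a ``cytoplasm_area_px2`` column spanning both sides of
    5000 px^2. Returns ``(matrix, truth)`` where truth has ``cell_id``
    and ``cell_type``.
    """
    if n_cells < 10:
        raise ValueError("n_cells must be >= 10")
    if spec is None:
        spec = SingleCellSpec()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    is_hep = rng.random(n_cells) < spec.hepatocyte_fraction
    area = np.where(
        is_hep,
        rng.normal(*spec.hepatocyte_area, size=n_cells),
        rng.normal(*spec.cholangiocyte_area, size=n_cells),
    )
    area = np.clip(area, 200.0, None)
    droplet_count = rng.poisson(spec.droplet_count_mean, size=n_cells)
    droplet_size = np.clip(
        rng.normal(*spec.droplet_size, size=n_cells), 1.0, None)
    mito = np.clip(rng.normal(*spec.mito_intensity, size=n_cells), 0, None)
    ox_mu, ox_sd = spec.oxstress_intensity
    oxstress = np.clip(
        ox_mu + spec.oxstress_droplet_slope
        * (droplet_size - spec.droplet_size[0])
        + rng.normal(0, ox_sd, size=n_cells),
        0, None)

    data = {
        "cell_id": np.arange(1, n_cells + 1),
        "cytoplasm_area_px2": area,
        "droplet_count": droplet_count.astype(float),
        "droplet_size_px2": droplet_size,
        "mito_intensity": mito,
        "oxstress_intensity": oxstress,
    }
    # filler features in the measured families; cell-type shifted so the
    # two populations also separate in feature space
    fams = ["intensity", "shape", "texture"]
    for j in range(spec.n_noise_features):
        fam = fams[j % 3]
        shift = (0.8 if j % 5 == 0 else 0.0) * (~is_hep)
        data[f"{fam}_f{j:02d}"] = rng.normal(0, 1, size=n_cells) + shift
    df = pd.DataFrame(data)

    for j in range(spec.n_constant_columns):
        df[f"constant_c{j:02d}"] = 1.0
    for j in range(spec.n_nan_columns):
        col = rng.normal(0, 1, size=n_cells)
        mask = rng.random(n_cells) < spec.nan_fraction
        col[mask] = np.nan
        df[f"sparse_c{j:02d}"] = col

    truth = pd.DataFrame({
        "cell_id": df["cell_id"],
        "cell_type": np.where(is_hep, "hepatocyte", "cholangiocyte"),
    })
    return df, truth


def generate_nucleus_features(
    n_healthy: int,
    n_apoptotic: int,
    separation: float = 3.0,
    n_features: int = 8,
    seed: int | np.random.Generator | None = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Separable nucleus feature vectors for apoptosis-classifier tests.

    Healthy and apoptotic nuclei are Gaussian clouds whose means differ
    by ``separation`` SDs in half the features (mimicking lower solidity
    / higher fragmentation scores of apoptotic nuclei). Returns
    ``(features, labels)`` with labels 1 = apoptotic.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = n_healthy + n_apoptotic
    y = np.concatenate([np.zeros(n_healthy, int), np.ones(n_apoptotic, int)])
    X = rng.normal(0, 1, size=(n, n_features))
    shifted = np.arange(n_features) % 2 == 0
    X[np.ix_(y == 1, shifted)] += separation
    cols = [f"nuc_feat_{j:02d}" for j in range(n_features)]
    return pd.DataFrame(X, columns=cols), y


# ---------------------------------------------------------------------------
# PK truth sets


@dataclass(frozen=True)
class PKTruthChemical:
    """A synthetic chemical with known PK parameters and simulated in vivo Css.

    ``simulated_in_vivo_css`` plays the role of a published in vivo
    measurement: the model-implied Css at the stated dose rate, perturbed
    by log-normal error of ``log10_error_sd`` decades.
    """

    name: str
    fup: float
    clint: float
    r_blood2plasma: float
    mw: float
    simulated_in_vivo_css: float
    true_css: float
    dose_mg_per_kg_day: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.fup <= 1:
            raise ValueError("fup must be in (0, 1]")
        if self.clint < 0:
            raise ValueError("clint must be >= 0")
        if self.mw <= 0:
            raise ValueError("mw must be > 0")

    def to_chemical_pk(self) -> ChemicalPK:
        return ChemicalPK(self.name, self.fup, self.clint,
                          self.r_blood2plasma, self.mw)


def generate_pk_truth_set(
    n: int,
    seed: int | np.random.Generator | None = 0,
    log10_error_sd: float = 0.69,
    dose: float = 1.0,
    phys: PhysiologyParams | None = None,
) -> list[PKTruthChemical]:
    """Chemicals with log-uniform fup and Clint and a noisy in vivo Css.

    fup is log-uniform on [0.005, 1], Clint log-uniform on [0.1, 200]
    ul/min/10^6 cells; the "observed" in vivo Css is the model Css at
    ``dose`` times 10^N(0, ``log10_error_sd``). With the error SD at 0,
    forward-dosimetry evaluation recovers R^2 = 1 exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if phys is None:
        phys = PhysiologyParams()
    out = []
    for i in range(n):
        fup = float(10 ** rng.uniform(np.log10(0.005), 0.0))
        clint = float(10 ** rng.uniform(np.log10(0.1), np.log10(200.0)))
        r = float(rng.uniform(0.7, 1.5))
        mw = float(rng.uniform(100.0, 500.0))
        chem = ChemicalPK(f"chem_{i:03d}", fup, clint, r, mw)
        css_true = calc_css(chem, phys, ko=dose)
        err = float(rng.normal(0.0, log10_error_sd)) if log10_error_sd > 0 else 0.0
        out.append(PKTruthChemical(
            name=chem.name, fup=fup, clint=clint, r_blood2plasma=r, mw=mw,
            simulated_in_vivo_css=css_true * 10 ** err, true_css=css_true,
            dose_mg_per_kg_day=dose))
    return out
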