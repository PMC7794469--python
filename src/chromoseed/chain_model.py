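"""Physical polymer representation of the chromatin fiber.

The fiber is modelled as a self-avoiding chain of tangent spheres: each
bead represents one Hi-C bin (2 kb or 5 kb of DNA), consecutive bead
centers sit exactly one bead diameter apart, non-adjacent centers may
not come closer than one diameter, and all centers are confined to a
sphere whose volume is the cell's nuclear volume scaled by the fraction
of the genome the region represents.

Defaults follow a beads-on-a-string fiber with mass density 165 bp per
11 nm and a bead diameter of 25 nm; two beads are considered in contact
(ligatable in Hi-C) when their centers are within 80 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

__all__ = [
    "PhysicalParams",
    "Conformation",
    "Ensemble",
    "CELL_PRESETS",
    "params_for_cell",
    "derive_geometry",
    "derive_confinement",
    "validate_conformation",
    "write_xyz",
    "read_xyz",
    "write_ensemble_h5",
    "read_ensemble_h5",
]

#: nuclear volume (um^3) and ploidy-adjusted genome size (Mb) per cell type
CELL_PRESETS: dict[str, tuple[float, float]] = {
    "pre-mbt": (335.0, 350.0),   # Drosophila embryo, nuclear cycles 9-13, diploid
    "post-mbt": (524.0, 350.0),  # embryo stages 5-8, diploid
    "s2r+": (292.0, 700.0),      # S2R+ cell line, tetraploid
}


def derive_geometry(resolution_bp: float, density: float = 165.0 / 11.0) -> float:
    """Contour length of fiber per bead (nm) from bin size and mass density."""
    if resolution_bp <= 0 or density <= 0:
        raise ValueError("resolution and density must be positive")
    return resolution_bp / density


def derive_confinement(nuclear_volume_um3: float, genome_size_mb: float,
                       region_length_mb: float) -> float:
    """Radius (nm) of the confining sphere for a region.

    The confining volume is the nuclear volume scaled by the genomic
    fraction the region occupies: V = V_nuc * (region / genome); the
    radius is that of the sphere of volume V.
    """
    if min(nuclear_volume_um3, genome_size_mb, region_length_mb) <= 0:
        raise ValueError("all inputs must be positive")
    if region_length_mb > genome_size_mb:
        raise ValueError("region cannot exceed genome size")
    v_um3 = nuclear_volume_um3 * region_length_mb / genome_size_mb
    radius_um = (3.0 * v_um3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return radius_um * 1e3


@dataclass(frozen=True)
class PhysicalParams:
    """Bead geometry, confinement and contact criterion."""

    resolution_bp: int = 2000
    bead_diameter_nm: float = 25.0
    fiber_density: float = 165.0 / 11.0  # bp per nm of fiber
    ligation_threshold_nm: float = 80.0
    nuclear_volume_um3: float | None = None
    genome_size_mb: float | None = None
    confinement_radius_nm: float | None = None

    def __post_init__(self) -> None:
        if self.bead_diameter_nm <= 0:
            raise ValueError("bead diameter must be positive")
        if self.ligation_threshold_nm < self.bead_diameter_nm:
            raise ValueError("ligation threshold must be >= bead diameter")

    def with_region(self, region_length_mb: float) -> "PhysicalParams":
        """Return a copy with the confinement radius derived for a region."""
        if self.nuclear_volume_um3 is None or self.genome_size_mb is None:
            raise ValueError("nuclear volume and genome size required")
        r = derive_confinement(self.nuclear_volume_um3, self.genome_size_mb,
                               region_length_mb)
        return replace(self, confinement_radius_nm=r)

    @property
    def radius(self) -> float:
        if self.confinement_radius_nm is None:
            raise ValueError("confinement radius not set")
        return self.confinement_radius_nm


def params_for_cell(cell: str, resolution_bp: int = 2000,
                    region_length_mb: float | None = None) -> PhysicalParams:
    """Physical parameters for a built-in cell preset."""
    vol, genome = CELL_PRESETS[cell]
    p = PhysicalParams(resolution_bp=resolution_bp, nuclear_volume_um3=vol,
                       genome_size_mb=genome)
    if region_length_mb is not None:
        p = p.with_region(region_length_mb)
    return p


@dataclass
class Conformation:
    """One 3D chain: ordered bead coordinates (nm) and an importance weight."""

    coords: np.ndarray
    weight: float = 1.0
    rng_seed: int = -1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.weight < 0:
            raise ValueError("weight must be non-negative")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]


@dataclass
class Ensemble:
    """A weighted set of equal-length conformations."""

    conformations: list[Conformation]
    params: PhysicalParams
    kind: str = "null"  # {null, constrained}
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.conformations:
            n = self.conformations[0].n_beads
            if any(c.n_beads != n for c in self.conformations):
                raise ValueError("all conformations must have equal length")
            if self.total_weight <= 0:
                raise ValueError("total weight must be positive")

    def __len__(self) -> int:
        return len(self.conformations)

    def __iter__(self) -> Iterator[Conformation]:
        return iter(self.conformations)

    @property
    def n_beads(self) -> int:
        return self.conformations[0].n_beads

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.conformations])

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    @property
    def coords_array(self) -> np.ndarray:
        """All coordinates stacked, shape (N, n_beads, 3)."""
        return np.stack([c.coords for c in self.conformations])

    @property
    def effective_sample_size(self) -> float:
        w = self.weights
        return float(w.sum() ** 2 / (w ** 2).sum())


@dataclass
class ValidationReport:
    bond_ok: bool
    self_avoidance_ok: bool
    confinement_ok: bool
    first_violation: tuple | None = None

    @property
    def ok(self) -> bool:
        return self.bond_ok and self.self_avoidance_ok and self.confinement_ok


def validate_conformation(conf: Conformation, params: PhysicalParams,
                          atol: float = 1e-6) -> ValidationReport:
    """Check bond lengths, self-avoidance and confinement of one chain.

    Bonds must equal the bead diameter to within ``atol`` nm; non-adjacent
    centers must be at least one diameter apart (a matching slack is
    allowed); every center must lie inside the confinement sphere.
    """
    x = conf.coords
    d = params.bead_diameter_nm
    report = ValidationReport(True, True, True)
    if x.shape[0] >= 2:
        bonds = np.linalg.norm(np.diff(x, axis=0), axis=1)
        bad = np.abs(bonds - d) > atol
        if bad.any():
            report.bond_ok = False
            report.first_violation = ("bond", int(np.argmax(bad)))
            return report
    n = x.shape[0]
    if n >= 3:
        for i in range(n - 2):
            dist = np.linalg.norm(x[i + 2:] - x[i], axis=1)
            viol = dist < d - atol
            if viol.any():
                report.self_avoidance_ok = False
                report.first_violation = ("self_avoidance",
                                          (i, i + 2 + int(np.argmax(viol))))
                return report
    if params.confinement_radius_nm is not None:
        r = np.linalg.norm(x, axis=1)
        out = r > params.confinement_radius_nm + atol
        if out.any():
            report.confinement_ok = False
            report.first_violation = ("confinement", int(np.argmax(out)))
    return report


# ---------------------------------------------------------------------------
# I/O


def write_xyz(ensemble: Ensemble, path) -> None:
    """Multi-record XYZ export: one record per conformation."""
    with open(path, "w") as fh:
        for k, conf in enumerate(ensemble):
            fh.write(f"{conf.n_beads}\n")
            fh.write(f"conformation {k} weight {conf.weight:.8g}\n")
            for i, (x, y, z) in enumerate(conf.coords):
                fh.write(f"{i} {x:.4f} {y:.4f} {z:.4f}\n")


def read_xyz(path, params: PhysicalParams | None = None) -> Ensemble:
    confs = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        n = int(lines[pos])
        header = lines[pos + 1].split()
        weight = float(header[header.index("weight") + 1]) if "weight" in header else 1.0
        coords = np.array([[float(v) for v in lines[pos + 2 + i].split()[1:4]]
                           for i in range(n)])
        confs.append(Conformation(coords=coords, weight=weight))
        pos += 2 + n
    return Ensemble(conformations=confs, params=params or PhysicalParams())


def write_ensemble_h5(ensemble: Ensemble, path) -> None:
    """HDF5 container: /coords [N, n, 3], /weights [N], /meta attrs."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=ensemble.coords_array)
        f.create_dataset("weights", data=ensemble.weights)
        meta = f.create_group("meta")
        meta.attrs["kind"] = ensemble.kind
        meta.attrs["bead_diameter_nm"] = ensemble.params.bead_diameter_nm
        meta.attrs["ligation_threshold_nm"] = ensemble.params.ligation_threshold_nm
        if ensemble.params.confinement_radius_nm is not None:
            meta.attrs["confinement_radius_nm"] = ensemble.params.confinement_radius_nm
        for key, val in ensemble.provenance.items():
            if isinstance(val, (int, float, str)):
                meta.attrs[f"prov_{key}"] = val


def read_ensemble_h5(path) -> Ensemble:
    import h5py

    with h5py.File(path, "r") as f:
        coords = f["coords"][:]
        weights = f["weights"][:]
        meta = dict(f["meta"].attrs)
    params = PhysicalParams(
        bead_diameter_nm=float(meta.get("bead_diameter_nm", 25.0)),
        ligation_threshold_nm=float(meta.get("ligation_threshold_nm", 80.0)),
        confinement_radius_nm=(float(meta["confinement_radius_nm"])
                               if "confinement_radius_nm" in meta else None),
    )
    confs = [Conformation(coords=coords[k], weight=float(weights[k]))
             for k in range(coords.shape[0])]
    prov = {k[5:]: v for k, v in meta.items() if k.startswith("prov_")}
    return Ensemble(conformations=confs, params=params,
                    kind=str(meta.get("kind", "null")), provenance=prov)
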