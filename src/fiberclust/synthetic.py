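"""Synthetic roots: regions with holes and centroid patterns with known truth.

No segmented histology is distributed with the package, so every statistic
and the cluster extractor are exercised against generated data whose
ground truth is known by construction:

* :func:`synthetic_region` — an irregular star-shaped "endoneurium" contour
  with circular vascular holes, sized like a primate ventral root cross-
  section (a few hundred µm across).
* :func:`generate_csr` — the null pattern itself (uniform placements).
* :func:`generate_clustered` — a parent-offspring (Thomas-style) process:
  a diffuse uniform background plus Gaussian clumps around uniform parent
  locations.  It has a CSR limit (no parents, or dispersion at region
  scale) and an interpretable strength knob (offspring dispersion), which
  is why it stands in for true fiber clumping.
* :func:`generate_mock_root` — a full Root with three diameter classes
  whose small-fiber (PPN) subpopulation is clustered to a requested
  strength while the large-fiber class stays CSR, echoing the empirical
  pattern that small autonomic fibers clump most.

Offspring falling outside the region are re-sampled, not discarded, so the
realized point count always matches the request.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import ClassBands, classify_fiber
from .geometry import Fascicle, FiberClass, FiberRecord, Region, Root
from .null import sample_uniform_points

__all__ = [
    "BACKGROUND",
    "SyntheticPattern",
    "synthetic_region",
    "generate_csr",
    "generate_clustered",
    "generate_mock_root",
]

#: truth label for diffuse (non-clustered) points
BACKGROUND = -1


@dataclass(frozen=True)
class SyntheticPattern:
    """Generated centroids plus ground-truth cluster memberships."""

    points: np.ndarray  # (n, 2) µm
    true_labels: np.ndarray  # (n,) parent index or BACKGROUND
    region: Region
    generator_params: dict = field(default_factory=dict)
    diameters: np.ndarray | None = None  # optional per-point µm

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    def to_fascicle(self, fascicle_id: str = "F1", bands: ClassBands | None = None) -> Fascicle:
        """Wrap as a Fascicle; diameters (if present) set fiber classes."""
        bands = bands or ClassBands()
        fibers = []
        for i, (x, y) in enumerate(self.points):
            d = None if self.diameters is None else float(self.diameters[i])
            fibers.append(
                FiberRecord(
                    fiber_id=f"f{i:05d}",
                    x=float(x),
                    y=float(y),
                    diameter=d,
                    fiber_class=(
                        classify_fiber(d, bands) if d is not None else FiberClass.UNASSIGNED
                    ),
                )
            )
        return Fascicle(region=self.region, fibers=fibers, fascicle_id=fascicle_id)


def synthetic_region(
    diameter: float = 400.0,
    n_vertices: int = 24,
    irregularity: float = 0.12,
    n_holes: int = 2,
    hole_radius_frac: float = 0.05,
    name: str = "synthetic-root",
    random_state=None,
) -> Region:
    """Irregular star-shaped contour with circular vascular holes.

    The outer ring perturbs a circle of the given diameter (µm) radially
    by +/- ``irregularity``; holes are circles of radius
    ``hole_radius_frac * diameter`` placed on fixed interior offsets, so
    two calls with the same arguments give the same region.
    """
    rng = np.random.default_rng(random_state)
    r0 = diameter / 2.0
    angles = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    radii = r0 * (1.0 + irregularity * rng.uniform(-1.0, 1.0, size=n_vertices))
    outer = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    # fixed interior anchors keep holes well inside even for irregular outers
    anchors = np.array([(-0.35, 0.15), (0.3, -0.3), (0.05, 0.4), (-0.2, -0.35)])
    holes = []
    hr = hole_radius_frac * diameter
    t = np.linspace(0.0, 2.0 * np.pi, 20, endpoint=False)
    circle = np.column_stack([np.cos(t), np.sin(t)])
    for ax, ay in anchors[:n_holes]:
        holes.append(np.array([ax * r0, ay * r0]) + hr * circle)
    return Region(outer=outer, holes=tuple(holes), name=name)


def generate_csr(region: Region, n: int, rng) -> SyntheticPattern:
    """n uniform points in the admissible area, all labeled BACKGROUND."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pts = sample_uniform_points(region, n, rng)
    return SyntheticPattern(
        points=pts,
        true_labels=np.full(n, BACKGROUND, dtype=int),
        region=region,
        generator_params={"model": "csr", "n": n},
    )


def _gaussian_offspring_in_region(
    region: Region, parent: np.ndarray, count: int, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Isotropic Gaussian displacements, rejection-resampled into the region."""
    out = np.empty((count, 2))
    got = 0
    while got < count:
        m = max(2 * (count - got), 8)
        cand = parent + rng.normal(0.0, sd, size=(m, 2))
        ok = region.contains_xy(cand[:, 0], cand[:, 1])
        acc = cand[ok]
        take = min(count - got, acc.shape[0])
        out[got : got + take] = acc[:take]
        got += take
    return out


def generate_clustered(
    region: Region,
    n_background: int,
    n_parents: int,
    children_mean: float,
    dispersion_sd: float,
    rng,
) -> SyntheticPattern:
    """Parent-offspring (Thomas-style) pattern over a uniform background.

    Parents are uniform in the region (latent — they are not emitted as
    points); each spawns Poisson(``children_mean``) offspring displaced by
    an isotropic Gaussian of scale ``dispersion_sd`` (µm) and re-sampled
    until inside the region.  Offspring carry their parent index as truth
    label; background points are BACKGROUND.
    """
    if n_parents < 0:
        raise ValueError("n_parents must be >= 0")
    if dispersion_sd <= 0:
        raise ValueError("dispersion_sd must be > 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    parents = sample_uniform_points(region, n_parents, rng)
    chunks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for j in range(n_parents):
        c = int(rng.poisson(children_mean))
        if c == 0:
            continue
        chunks.append(_gaussian_offspring_in_region(region, parents[j], c, dispersion_sd, rng))
        labels.append(np.full(c, j, dtype=int))
    bg = sample_uniform_points(region, n_background, rng)
    chunks.append(bg)
    labels.append(np.full(n_background, BACKGROUND, dtype=int))
    points = np.vstack(chunks) if chunks else np.empty((0, 2))
    return SyntheticPattern(
        points=points,
        true_labels=np.concatenate(labels) if labels else np.empty(0, dtype=int),
        region=region,
        generator_params={
            "model": "thomas",
            "n_background": n_background,
            "n_parents": n_parents,
            "children_mean": children_mean,
            "dispersion_sd": dispersion_sd,
            "parents": parents.tolist(),
        },
    )


def _draw_diameters(klass: FiberClass, size: int, rng: np.random.Generator) -> np.ndarray:
    """Per-class diameter draws (µm) spanning the three bands.

    PPN: lognormal around ~2 µm truncated to (0, 4]; GAMMA: mid-band beta
    over (4, 10]; ALPHA: right-skewed beta over (10, 20], the upper end
    matching the largest myelinated fibers seen in these roots.
    """
    if klass == FiberClass.PPN:
        out = np.empty(size)
        got = 0
        while got < size:
            d = rng.lognormal(mean=np.log(2.0), sigma=0.45, size=2 * (size - got) + 4)
            d = d[(d > 0.4) & (d <= 4.0)]
            take = min(size - got, d.size)
            out[got : got + take] = d[:take]
            got += take
        return out
    if klass == FiberClass.GAMMA:
        return 4.0 + 6.0 * rng.beta(2.0, 2.0, size=size)
    return 10.0 + 10.0 * rng.beta(1.6, 2.8, size=size)


def generate_mock_root(
    n_total: int = 1000,
    ppn_frac: float = 0.38,
    gamma_frac: float = 0.20,
    cluster_strength: float = 0.8,
    region: Region | None = None,
    root_id: str = "S1-mock",
    animal_id: str = "A0",
    random_state=None,
) -> tuple[Root, SyntheticPattern]:
    """A full mock root: three diameter classes, clustered PPN subpopulation.

    Class counts are multinomial draws at (ppn_frac, gamma_frac, rest).
    ``cluster_strength`` in [0, 1] is the fraction of PPN fibers placed in
    compact parent-offspring clumps (dispersion 1.5% of the region
    diameter, ~15 offspring per parent); the remaining PPN fibers and the
    two motor classes are uniform, so strength 0 reduces every class to
    CSR.  Returns the Root and the underlying pattern with truth labels.
    """
    if not (0.0 <= ppn_frac <= 1.0 and 0.0 <= gamma_frac <= 1.0 and ppn_frac + gamma_frac <= 1.0):
        raise ValueError("fractions must be in [0, 1] and sum to <= 1")
    if not 0.0 <= cluster_strength <= 1.0:
        raise ValueError("cluster_strength must be in [0, 1]")
    ss = (
        random_state
        if isinstance(random_state, np.random.SeedSequence)
        else np.random.SeedSequence(random_state)
    )
    rng = np.random.default_rng(ss)
    region = region or synthetic_region(random_state=np.random.default_rng(12345))
    n_ppn, n_gamma, n_alpha = rng.multinomial(
        n_total, [ppn_frac, gamma_frac, 1.0 - ppn_frac - gamma_frac]
    )

    xmin, ymin, xmax, ymax = region.bounds
    region_diam = float(np.hypot(xmax - xmin, ymax - ymin))
    n_clumped = int(round(cluster_strength * n_ppn))
    children_mean = 15.0
    n_parents = max(1, int(round(n_clumped / children_mean))) if n_clumped > 0 else 0

    pieces: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    classes: list[FiberClass] = []
    diams: list[np.ndarray] = []
    if n_ppn > 0:
        # exact class counts: split the clumped quota over parents
        # multinomially instead of Poisson so totals are conserved
        ppn_pts = [sample_uniform_points(region, n_ppn - n_clumped, rng)]
        ppn_lab = [np.full(n_ppn - n_clumped, BACKGROUND, dtype=int)]
        if n_parents > 0:
            parents = sample_uniform_points(region, n_parents, rng)
            per_parent = rng.multinomial(n_clumped, np.full(n_parents, 1.0 / n_parents))
            for j, c in enumerate(per_parent):
                if c == 0:
                    continue
                ppn_pts.append(
                    _gaussian_offspring_in_region(
                        region, parents[j], int(c), 0.015 * region_diam, rng
                    )
                )
                ppn_lab.append(np.full(int(c), j, dtype=int))
        ppn_points = np.vstack(ppn_pts)
        pieces.append(ppn_points)
        labels.append(np.concatenate(ppn_lab))
        classes += [FiberClass.PPN] * n_ppn
        diams.append(_draw_diameters(FiberClass.PPN, n_ppn, rng))
    for klass, count in ((FiberClass.GAMMA, n_gamma), (FiberClass.ALPHA, n_alpha)):
        if count == 0:
            continue
        pieces.append(sample_uniform_points(region, count, rng))
        labels.append(np.full(count, BACKGROUND, dtype=int))
        classes += [klass] * count
        diams.append(_draw_diameters(klass, count, rng))

    points = np.vstack(pieces) if pieces else np.empty((0, 2))
    diameters = np.concatenate(diams) if diams else np.empty(0)
    pattern = SyntheticPattern(
        points=points,
        true_labels=np.concatenate(labels) if labels else np.empty(0, dtype=int),
        region=region,
        diameters=diameters,
        generator_params={
            "model": "mock-root",
            "n_total": n_total,
            "ppn_frac": ppn_frac,
            "gamma_frac": gamma_frac,
            "cluster_strength": cluster_strength,
        },
    )
    fibers = [
        FiberRecord(
            fiber_id=f"f{i:05d}",
            x=float(points[i, 0]),
            y=float(points[i, 1]),
            diameter=float(diameters[i]),
            fiber_class=classes[i],
        )
        for i in range(points.shape[0])
    ]
    fascicle = Fascicle(region=region, fibers=fibers, fascicle_id=f"{root_id}-F1")
    return Root(root_id=root_id, animal_id=animal_id, fascicles=[fascicle]), pattern
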