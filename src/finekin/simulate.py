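"""Forward-in-time, spatially explicit plant-population simulator.

Non-overlapping generations on a rectangular habitat divided into grid
cells of fixed carrying capacity (density regulation). Each offspring slot
is placed uniformly within its cell; its mother is drawn among the adults
with weights from an axial Gaussian seed kernel (backward dispersal, which
fills every cell exactly to capacity), its father by a Gaussian pollen
kernel centred on the mother (or the mother herself at the selfing rate).
Nuclear SSR alleles are transmitted Mendelian with stepwise mutation on a
bounded ladder; the plastid haplotype is strictly maternal. Scenarios add
two-deme secondary contact with assortative mating, an altitudinal
dispersal barrier, or null-allele masking at genotyping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import GenotypeMatrix, HaplotypeSet, SpatialFrame

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate",
    "sample_transect",
    "panmixia_config",
    "ibd_config",
    "two_deme_config",
    "altitudinal_config",
]


@dataclass
class SimulationConfig:
    width: float = 300.0  # habitat extent, metres
    height: float = 300.0
    cell_size: float = 30.0
    density: float = 0.01  # individuals per square metre (100 / ha)
    generations: int | None = None  # None: 10 x span / sigma_g
    sigma_seed: float = 20.0
    sigma_pollen: float = 20.0
    selfing: float = 0.0
    clonal_prob: float = 0.0
    n_loci: int = 5
    n_states: int = 40  # stepwise-mutation ladder size
    mu: float = 1e-3
    n_haplotypes: int = 5
    hap_mu: float = 1e-4
    null_rates: tuple[float, ...] = ()  # per-locus null-allele founder freq
    scenario: str = "ibd"  # panmixia | ibd | two_deme_contact | altitudinal_barrier
    fst_target: float = 0.15  # founder differentiation for two_deme_contact
    assortment: float = 0.0  # prob. a father is drawn from the mother's deme
    barrier_permeability: float = 1.0
    altitude_range: float = 0.0  # altitude climbs linearly with x over this range
    seed: int | None = None

    @property
    def sigma_g(self) -> float:
        """Axial SD of gene dispersal: sigma_seed^2 + sigma_pollen^2 / 2."""
        return float(np.sqrt(self.sigma_seed**2 + self.sigma_pollen**2 / 2.0))

    def n_generations(self) -> int:
        if self.generations is not None:
            return self.generations
        span = max(self.width, self.height)
        return int(np.ceil(10.0 * span / max(self.sigma_g, 1e-9)))


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    spatial: SpatialFrame
    haplotypes: HaplotypeSet
    truth: dict = field(default_factory=dict)


def _row_categorical(rng: np.random.Generator, w: np.ndarray) -> np.ndarray:
    """One categorical draw per row of the (unnormalised) weight matrix."""
    cum = np.cumsum(w, axis=1)
    tot = cum[:, -1:]
    bad = tot[:, 0] <= 0
    if bad.any():  # no reachable parent: fall back to uniform
        w = w.copy()
        w[bad] = 1.0
        cum = np.cumsum(w, axis=1)
        tot = cum[:, -1:]
    r = rng.random((w.shape[0], 1)) * tot
    return (r > cum).sum(axis=1)


def _kernel(
    dx2: np.ndarray, sigma: float, crossings: np.ndarray | None, permeability: float
) -> np.ndarray:
    if sigma <= 0:
        w = (dx2 == dx2.min(axis=1, keepdims=True)).astype(float)
    else:
        w = np.exp(-dx2 / (2.0 * sigma * sigma))
    if crossings is not None and permeability < 1.0:
        w = w * np.where(crossings, permeability, 1.0)
    return w


def simulate(cfg: SimulationConfig) -> SimulatedDataset:
    """Run the forward simulation and emit a genotyped, georeferenced
    population with its plastid haplotypes and a truth record."""
    rng = np.random.default_rng(cfg.seed)
    nx = max(1, round(cfg.width / cfg.cell_size))
    ny = max(1, round(cfg.height / cfg.cell_size))
    cap = max(1, round(cfg.density * cfg.cell_size**2))
    N = nx * ny * cap
    if N < 4:
        raise ValueError("habitat too small for a viable population")

    # founder placement: per cell-slot, uniform within the cell
    cell_x = np.repeat(np.arange(nx), ny * cap)
    cell_y = np.tile(np.repeat(np.arange(ny), cap), nx)

    def _slot_positions() -> tuple[np.ndarray, np.ndarray]:
        x = (cell_x + rng.random(N)) * (cfg.width / nx)
        y = (cell_y + rng.random(N)) * (cfg.height / ny)
        return x, y

    x, y = _slot_positions()

    two_deme = cfg.scenario == "two_deme_contact"
    barrier = cfg.scenario == "altitudinal_barrier"
    null_rates = np.zeros(cfg.n_loci)
    null_rates[: len(cfg.null_rates)] = cfg.null_rates[: cfg.n_loci]
    NULL = cfg.n_states  # sentinel allele state that fails to amplify

    # founder genotypes
    geno = np.empty((N, cfg.n_loci, 2), dtype=int)
    deme = (x > cfg.width / 2).astype(int) if two_deme else np.zeros(N, dtype=int)
    ancestry = deme.astype(float)
    for l in range(cfg.n_loci):
        if two_deme:
            base = rng.dirichlet(np.ones(10))
            f = min(max(cfg.fst_target, 1e-3), 0.99)
            conc = base * (1.0 - f) / f
            p0 = rng.dirichlet(conc)
            p1 = rng.dirichlet(conc)
            for d_, p in ((0, p0), (1, p1)):
                sel = deme == d_
                geno[sel, l, :] = rng.choice(10, size=(sel.sum(), 2), p=p)
        else:
            geno[:, l, :] = rng.integers(0, cfg.n_states, size=(N, 2))
        if null_rates[l] > 0:
            mask = rng.random((N, 2)) < null_rates[l]
            geno[:, l, :][mask] = NULL

    if two_deme:
        hap = deme.copy()  # deme-specific founder haplotypes
        next_hap = 2
    else:
        hap = rng.integers(0, cfg.n_haplotypes, size=N)
        next_hap = cfg.n_haplotypes

    alt_of = (
        (lambda xx: cfg.altitude_range * xx / cfg.width)
        if cfg.altitude_range > 0 or barrier
        else None
    )
    barrier_x = cfg.width / 2  # contour at the mid altitude

    for gen in range(cfg.n_generations()):
        if N == 0:
            raise RuntimeError(f"population extinct at generation {gen}")
        ox, oy = _slot_positions()
        dx2 = (ox[:, None] - x[None, :]) ** 2 + (oy[:, None] - y[None, :]) ** 2
        crossings = None
        if barrier and cfg.barrier_permeability < 1.0:
            crossings = (ox[:, None] > barrier_x) != (x[None, :] > barrier_x)
        w_seed = _kernel(dx2, cfg.sigma_seed, crossings, cfg.barrier_permeability)
        mothers = _row_categorical(rng, w_seed)

        mx, my = x[mothers], y[mothers]
        dpx2 = (mx[:, None] - x[None, :]) ** 2 + (my[:, None] - y[None, :]) ** 2
        crossings_p = None
        if barrier and cfg.barrier_permeability < 1.0:
            crossings_p = (mx[:, None] > barrier_x) != (x[None, :] > barrier_x)
        w_pol = _kernel(dpx2, cfg.sigma_pollen, crossings_p, cfg.barrier_permeability)
        w_pol[np.arange(N), mothers] = 0.0  # selfing handled explicitly
        if two_deme and cfg.assortment > 0:
            same = deme[mothers][:, None] == deme[None, :]
            assorted = rng.random(N) < cfg.assortment
            w_pol = np.where(assorted[:, None] & ~same, 0.0, w_pol)
        fathers = _row_categorical(rng, w_pol)
        selfed = rng.random(N) < cfg.selfing
        fathers[selfed] = mothers[selfed]

        clonal = rng.random(N) < cfg.clonal_prob

        pick_m = rng.integers(0, 2, size=(N, cfg.n_loci))
        pick_f = rng.integers(0, 2, size=(N, cfg.n_loci))
        lr = np.arange(cfg.n_loci)[None, :]
        new = np.empty_like(geno)
        new[:, :, 0] = geno[mothers[:, None], lr, pick_m]
        new[:, :, 1] = geno[fathers[:, None], lr, pick_f]
        # stepwise mutation on the bounded ladder; null alleles do not mutate
        mut = (rng.random((N, cfg.n_loci, 2)) < cfg.mu) & (new != NULL)
        step = rng.choice([-1, 1], size=(N, cfg.n_loci, 2))
        new = np.where(mut, np.clip(new + step, 0, cfg.n_states - 1), new)
        # clones copy the mother wholesale
        new[clonal] = geno[mothers[clonal]]

        new_hap = hap[mothers].copy()
        hmut = (rng.random(N) < cfg.hap_mu) & ~clonal
        n_new = int(hmut.sum())
        if n_new:
            new_hap[hmut] = np.arange(next_hap, next_hap + n_new)
            next_hap += n_new

        new_deme = deme[mothers]
        new_anc = (
            (ancestry[mothers] + ancestry[fathers]) / 2.0
            if two_deme
            else np.zeros(N)
        )
        new_anc[clonal] = ancestry[mothers[clonal]] if two_deme else 0.0

        x, y, geno, hap, deme, ancestry = ox, oy, new, new_hap, new_deme, new_anc

    ids = [f"ind{i + 1}" for i in range(N)]
    calls: list[list[tuple[str, str] | None]] = []
    for i in range(N):
        row: list[tuple[str, str] | None] = []
        for l in range(cfg.n_loci):
            a, b = geno[i, l]
            if a == NULL and b == NULL:
                row.append(None)  # whole-locus amplification failure
            elif a == NULL:
                row.append((str(100 + b), str(100 + b)))  # apparent homozygote
            elif b == NULL:
                row.append((str(100 + a), str(100 + a)))
            else:
                row.append((str(100 + a), str(100 + b)))
        calls.append(row)
    g = GenotypeMatrix(ids, [f"L{l + 1}" for l in range(cfg.n_loci)], calls)
    altitude = alt_of(x) if alt_of is not None else None
    s = SpatialFrame(ids, x, y, altitude, population=["sim"] * N)
    h = HaplotypeSet(ids, [f"H{v + 1}" for v in hap])
    truth = {
        "sigma_seed": cfg.sigma_seed,
        "sigma_pollen": cfg.sigma_pollen,
        "sigma_g": cfg.sigma_g,
        "density": cfg.density,
        "deme": deme.copy(),
        "ancestry": ancestry.copy(),
        "null_states": geno == NULL,
        "realized_null_freq": [
            float(np.mean(geno[:, l, :] == NULL)) for l in range(cfg.n_loci)
        ],
        "config": cfg,
    }
    return SimulatedDataset(g, s, h, truth)


def sample_transect(
    d: SimulatedDataset,
    n: int,
    design: str = "random",
    seed: int | None = None,
) -> SimulatedDataset:
    """Subsample the simulated world with a declared sampling design.

    ``random`` draws n individuals uniformly; ``transect`` takes the n
    individuals closest to the mid-habitat line (a strip following the
    long axis, emulating transect sampling along topographic features).
    """
    N = d.spatial.n_individuals
    if n > N:
        raise ValueError("sample larger than the population")
    if design == "random":
        rng = np.random.default_rng(seed)
        sel = np.sort(rng.choice(N, size=n, replace=False))
    elif design == "transect":
        y0 = (d.spatial.y.max() + d.spatial.y.min()) / 2.0
        sel = np.sort(np.argsort(np.abs(d.spatial.y - y0), kind="stable")[:n])
    else:
        raise ValueError(f"unknown design {design!r}")
    ids = [d.spatial.individual_ids[i] for i in sel]
    truth = dict(d.truth)
    for key in ("deme", "ancestry"):
        if key in truth and isinstance(truth[key], np.ndarray):
            truth[key] = truth[key][sel]
    if "null_states" in truth:
        truth["null_states"] = truth["null_states"][sel]
    return SimulatedDataset(
        d.genotypes.subset(ids), d.spatial.subset(ids), d.haplotypes.subset(ids), truth
    )


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------


def panmixia_config(seed: int | None = None, **kw) -> SimulationConfig:
    """Dispersal kernels as wide as the habitat: the calibrated null."""
    return replace(
        SimulationConfig(
            scenario="panmixia",
            width=300.0,
            height=300.0,
            sigma_seed=300.0,
            sigma_pollen=300.0,
            generations=30,
            seed=seed,
        ),
        **kw,
    )


def ibd_config(
    sp_target: float = 0.01, density: float = 0.01, seed: int | None = None, **kw
) -> SimulationConfig:
    """Isolation by distance tuned so 1/(4 pi D sigma_g^2) = sp_target.

    With equal seed and pollen kernels, sigma_g^2 = 1.5 sigma^2.
    """
    sigma_g2 = 1.0 / (4.0 * np.pi * density * sp_target)
    sigma = float(np.sqrt(sigma_g2 / 1.5))
    return replace(
        SimulationConfig(
            scenario="ibd",
            width=316.0,
            height=316.0,
            cell_size=31.6,
            density=density,
            sigma_seed=sigma,
            sigma_pollen=sigma,
            seed=seed,
        ),
        **kw,
    )


def two_deme_config(
    fst: float = 0.15, assortment: float = 0.9, seed: int | None = None, **kw
) -> SimulationConfig:
    """Secondary contact of two differentiated gene pools with deme-specific
    plastid haplotypes and assortative mating; few generations so the
    founder differentiation persists."""
    return replace(
        SimulationConfig(
            scenario="two_deme_contact",
            width=300.0,
            height=150.0,
            cell_size=30.0,
            density=0.01,
            sigma_seed=15.0,
            sigma_pollen=30.0,
            generations=3,
            fst_target=fst,
            assortment=assortment,
            seed=seed,
        ),
        **kw,
    )


def altitudinal_config(
    permeability: float = 0.1, seed: int | None = None, **kw
) -> SimulationConfig:
    """An altitudinal gradient along x with a partially permeable dispersal
    barrier at the mid-altitude contour."""
    return replace(
        SimulationConfig(
            scenario="altitudinal_barrier",
            width=400.0,
            height=200.0,
            cell_size=40.0,
            density=0.01,
            sigma_seed=20.0,
            sigma_pollen=40.0,
            barrier_permeability=permeability,
            altitude_range=500.0,
            seed=seed,
        ),
        **kw,
    )
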