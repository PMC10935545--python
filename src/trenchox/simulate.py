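"""Agent-based simulator of cells growing in mother-machine trenches under H2O2.

Model summary
-------------
Each trench is a 1-D stack of rod-shaped cells between a closed end (index 0,
the "mother cell") and an open end facing the flow channel.  External H2O2 at
concentration ``c0`` enters at the open end; every live scavenging cell j
between a focal cell and the opening removes a fraction

    f_j = 1 - exp(-sigma * S_j * E_j)

of the incoming flux, where ``S_j`` is the cell's surface area (hemisphere
capped cylinder) and ``E_j`` its scavenging-enzyme level, so the local
concentration behind a stack of barriers decays geometrically.  Intracellular
H2O2 relaxes quickly toward the local concentration divided by the cell's own
scavenging activity; it drives (i) delayed Hill induction of the enzyme and a
transcriptional reporter, (ii) Hill inhibition of elongation, (iii) an
absorbing death rule with an enzyme-dependent (primed) tolerance, and
(iv) a Poisson DNA-mismatch focus rate that bursts before induction.

Cells elongate exponentially, divide at twice their birth length (sizer with
lognormal noise), partition contents binomial-like between daughters, and are
pushed out of the open end.  Explicit Euler integration with 0.25 min
sub-steps inside each imaging frame.

The per-cell update rules are exposed as :func:`step_growth`,
:func:`step_response`, :func:`divide_and_push` and
:func:`step_fate_and_mismatch` operating on :class:`CellState`;
:func:`simulate` runs the vectorised engine over many trenches and emits a
track table (one row per live cell per frame).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig, TreatmentSchedule, config_digest

TRACK_COLUMNS = [
    "trench_id", "frame", "time_min", "cell_index", "cell_id", "lineage_id",
    "parent_id", "genotype", "length_um", "area_um2", "position_um",
    "reporter_au", "marker_au", "foci_count", "alive", "external_c0_uM",
]

_GENO_CODE = {"WT": 0, "delta_oxyR": 1, "inert": 2}
_GENO_NAME = {v: k for k, v in _GENO_CODE.items()}


class SimulationError(RuntimeError):
    """Raised when the simulator state becomes non-finite."""


def damkohler_number(scavenging_rate_per_s: float = 5.4e4,
                     length_m: float = 1.2e-6,
                     envelope_permeation_m_per_s: float = 1.6e-5) -> float:
    """Damkoehler number: intracellular scavenging rate over envelope transport.

    Values much greater than one mean scavenging is limited by diffusion of
    H2O2 into the cell, so a cell's protective effect scales with its surface
    area.  Defaults are the catalase turnover rate and the H2O2 permeation
    velocity of the E. coli envelope; ``k * L / v`` with the defaults is
    about 4e3.
    """
    if scavenging_rate_per_s < 0 or length_m <= 0 or envelope_permeation_m_per_s <= 0:
        raise ValueError("rates and lengths must be positive")
    return scavenging_rate_per_s * length_m / envelope_permeation_m_per_s


def hill(c, k: float, n: float):
    """Hill activation c^n / (c^n + k^n), zero for c <= 0."""
    c = np.maximum(np.asarray(c, dtype=float), 0.0)
    cn = np.where(c > 0, c ** n, 0.0)
    return cn / (cn + k ** n)


def surface_area(length_um, width_um: float):
    """Envelope surface area of a hemisphere-capped cylinder of radius w/2.

    For this geometry the area reduces to 2*pi*r*L; lengths below the
    diameter are clamped so short cells degrade to spheres of radius r.
    """
    r = width_um / 2.0
    L = np.maximum(np.asarray(length_um, dtype=float), 2.0 * r)
    return 2.0 * math.pi * r * L


def effective_sigma(config: SimConfig) -> float:
    """Attenuation scale corrected for trench width.

    A wider trench opens a disproportionately larger bypass gap around each
    cell (the free cross-section grows much faster than the width), so the
    attenuation scale falls steeply with width; the default exponent of 5
    comes from the ratio of free to cell cross-section areas at 1.2 versus
    1.4 um and is exposed in the config.
    """
    ratio = config.width_reference_um / config.trench_width_um
    return config.attenuation_scale * ratio ** config.width_bypass_exponent


@dataclass
class CellState:
    """Single-cell state for the op-level API (the engine uses arrays).

    ``reporter`` and ``marker`` are protein contents (a.u.); the recorded
    per-cell intensity is content divided by cell area, which is what a
    mean-over-mask fluorescence measurement reports.
    """

    cell_id: int = 0
    lineage_id: int = 0
    parent_id: int = -1
    genotype: str = "WT"
    length: float = 1.8             # um
    position: float = 0.0           # um, proximal edge from the closed end
    elongation_rate: float = 0.028  # min^-1
    enzyme_level: float = 0.02
    reporter: float = 0.0           # a.u. content
    marker: float = 0.0
    internal_h2o2: float = 0.0      # uM
    alive: bool = True
    birth_length: float = 1.8
    division_length: float = 3.6
    excess_time: float = 0.0        # consecutive minutes above lethal tolerance
    sensed_history: list = field(default_factory=list)

    def scavenging(self) -> float:
        """Enzyme level entering the shielding law; inert and dead cells do
        not scavenge."""
        if not self.alive or self.genotype == "inert":
            return 0.0
        return self.enzyme_level

    def area(self, config: SimConfig) -> float:
        return 2.0 * (config.trench_width_um / 2.0) * self.length


def attenuation_fraction(cell: CellState, config: SimConfig) -> float:
    """Fraction of incoming H2O2 removed by one cell, f in [0, 1)."""
    e = cell.scavenging()
    if config.attenuation_mode == "fixed":
        return config.fixed_attenuation if e > 0 else 0.0
    s = float(surface_area(cell.length, config.trench_width_um))
    return 1.0 - math.exp(-effective_sigma(config) * s * e)


def h2o2_profile(cells_ordered_from_open_end: list[CellState], c0: float,
                 config: SimConfig) -> list[float]:
    """Local H2O2 concentration at each cell, open end first.

    The cell nearest the opening sees ``c0``; each subsequent cell sees the
    previous concentration multiplied by (1 - f) of every cell in front of
    it.  Empty input yields an empty profile.
    """
    if c0 < 0:
        raise ValueError(f"negative external concentration: {c0}")
    out: list[float] = []
    c = float(c0)
    for cell in cells_ordered_from_open_end:
        out.append(c)
        c *= 1.0 - attenuation_fraction(cell, config)
    return out


def _growth_factor(c_int, config: SimConfig):
    gi = config.growth_inhibition
    c = np.maximum(np.asarray(c_int, dtype=float), 0.0)
    return 1.0 / (1.0 + (c / gi.k_uM) ** gi.exponent)


def _damage_factor(c_int, config: SimConfig):
    """Saturating slowdown of all protein synthesis under severe stress."""
    e = config.enzyme
    c = np.maximum(np.asarray(c_int, dtype=float), 0.0)
    return 1.0 / (1.0 + (c / e.damage_k_uM) ** e.damage_n)


def _internal_target(c_local, enzyme, config: SimConfig):
    """Quasi-steady intracellular concentration: influx balanced against the
    cell's own scavenging, c_loc / (1 + theta * E)."""
    return np.asarray(c_local, dtype=float) / (
        1.0 + config.internal_scavenging_strength * np.asarray(enzyme, dtype=float))


def step_growth(cell: CellState, c_local: float, dt: float, config: SimConfig,
                rng: np.random.Generator | None = None) -> CellState:
    """Relax intracellular H2O2 and elongate the cell for ``dt`` minutes.

    dL/dt = beta * L * g(c_int) with Hill inhibition g; the internal
    concentration relaxes exponentially (rate ``internal_relaxation_rate``)
    toward the local concentration reduced by the cell's own scavenging.
    Dead and inert cells do not elongate.  ``beta`` carries its
    (multiplicative) noise from birth, so this step is deterministic.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    target = float(_internal_target(c_local, cell.scavenging(), config))
    decay = math.exp(-config.internal_relaxation_rate * dt)
    cell.internal_h2o2 = target + (cell.internal_h2o2 - target) * decay
    if cell.alive and cell.genotype != "inert":
        g = float(_growth_factor(cell.internal_h2o2, config))
        cell.length *= math.exp(cell.elongation_rate * g * dt)
    return cell


def _sense(cell: CellState, dt: float, config: SimConfig) -> tuple[float, float]:
    """Delayed intracellular concentrations seen by the gene-expression layer.

    The cell keeps a short history of its internal concentration; enzyme
    induction responds to the value ``enzyme.delay_min`` ago and reporter
    production to the value ``reporter.delay_min`` ago (the extra delay is
    fluorophore maturation).  Values before any history exists are zero.
    """
    steps_e = int(round(config.enzyme.delay_min / dt))
    steps_r = int(round(config.reporter.delay_min / dt))
    keep = max(steps_e, steps_r) + 1
    cell.sensed_history.append(cell.internal_h2o2)
    if len(cell.sensed_history) > keep:
        del cell.sensed_history[: len(cell.sensed_history) - keep]

    def back(k: int) -> float:
        idx = len(cell.sensed_history) - 1 - k
        return cell.sensed_history[idx] if idx >= 0 else 0.0

    return back(steps_e), back(steps_r)


def step_response(cell: CellState, c_local: float, dt: float,
                  config: SimConfig) -> CellState:
    """Update enzyme level and reporter/marker contents for ``dt`` minutes.

    Both follow the same delayed Hill sensing of the internal concentration.
    The enzyme saturates at 1 and is diluted by growth; a delta_oxyR cell
    never induces (its level stays basal).  The reporter is produced at
    basal + induced rate, proportional to cell area, and removed only by
    growth dilution and division partitioning.  Larger enzyme levels lower
    the internal concentration at fixed local concentration (negative
    feedback, applied in :func:`step_growth`).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    sensed_e, sensed_r = _sense(cell, dt, config)
    if not cell.alive or cell.genotype == "inert":
        return cell
    enz, rep = config.enzyme, config.reporter
    g = float(_growth_factor(cell.internal_h2o2, config))
    dmg = float(_damage_factor(cell.internal_h2o2, config))
    if cell.genotype == "WT":
        h_e = float(hill(sensed_e, enz.hill_k_uM, enz.hill_n))
        dE = enz.max_rate * h_e * (1.0 - cell.enzyme_level) * dmg \
            - cell.elongation_rate * g * cell.enzyme_level
        cell.enzyme_level = float(np.clip(cell.enzyme_level + dE * dt,
                                          0.0, 1.0))
        cell.enzyme_level = max(cell.enzyme_level, enz.basal_level)
    area = cell.area(config)
    h_r = float(hill(sensed_r, rep.hill_k_uM, rep.hill_n))
    if cell.genotype == "WT":
        prod = rep.basal_rate + rep.max_induced_rate * h_r
    else:  # delta_oxyR: reporter stays basal (no OxyR induction)
        prod = rep.basal_rate
    cell.reporter += prod * dmg * area * dt
    cell.marker += config.marker_rate * dmg * area * dt
    return cell


def step_fate_and_mismatch(cell: CellState, dt: float, config: SimConfig,
                           rng: np.random.Generator) -> tuple[CellState, int]:
    """Death bookkeeping and Poisson mismatch-focus emission for ``dt`` min.

    Death occurs when the internal concentration stays above
    ``lethal + priming_coefficient * E`` continuously for the configured
    sustained duration; growth then stops permanently (the dead cell remains
    as non-scavenging mass).  Foci are emitted as Poisson(lambda * dt) with
    lambda = basal + induced * c_int * (1 - E), producing a burst before
    induction that subsides as the enzyme level rises.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    d = config.death
    if cell.alive and cell.genotype != "inert":
        tol = d.lethal_uM + d.priming_coefficient_uM * cell.enzyme_level
        if cell.internal_h2o2 > tol:
            cell.excess_time += dt
        else:
            cell.excess_time = 0.0
        if cell.excess_time >= d.sustained_min:
            cell.alive = False
    lam = config.mismatch.basal
    if cell.alive and cell.genotype != "inert":
        lam = lam + config.mismatch.induced_per_uM * max(cell.internal_h2o2, 0.0) \
            * (1.0 - cell.enzyme_level)
        foci = int(rng.poisson(lam * dt))
    else:
        foci = 0
    return cell, foci


def _partition(content: float, p: float) -> tuple[float, float]:
    return content * p, content * (1.0 - p)


def divide_and_push(trench: list[CellState], config: SimConfig,
                    rng: np.random.Generator,
                    id_counter: list[int] | None = None) -> list[CellState]:
    """Apply divisions, restack positions from the closed end, remove exits.

    ``trench`` is ordered from the closed end (mother first).  A cell divides
    when its length reaches its division length (2x birth length with
    lognormal noise); daughters split the length equally and partition
    reporter/enzyme/marker content with a fraction drawn around one half
    (SD ``partition_noise_sd``; the sum is conserved exactly).  The daughter
    closer to the closed end keeps the parent's stack slot.  Positions are
    recomputed by stacking lengths from the closed end and any cell whose
    proximal edge reaches the trench length is removed (exited).
    """
    if id_counter is None:
        id_counter = [max((c.cell_id for c in trench), default=0) + 1]
    out: list[CellState] = []
    for cell in trench:
        g_div = float(np.clip(_growth_factor(cell.internal_h2o2, config),
                          0.3, 1.0)) ** config.stress_size_exponent
        if (cell.alive and cell.genotype != "inert"
                and cell.length >= cell.division_length * g_div):
            p = float(np.clip(rng.normal(0.5, config.partition_noise_sd), 0.3, 0.7))
            pe = float(np.clip(rng.normal(0.5, config.partition_noise_sd), 0.3, 0.7))
            pm = float(np.clip(rng.normal(0.5, config.partition_noise_sd), 0.3, 0.7))
            half = cell.length / 2.0
            r1, r2 = _partition(cell.reporter, p)
            m1, m2 = _partition(cell.marker, pm)
            e1 = float(np.clip(2.0 * pe * cell.enzyme_level, 0.0, 1.0))
            e2 = float(np.clip(2.0 * (1.0 - pe) * cell.enzyme_level, 0.0, 1.0))
            daughters = []
            for (rep, mar, enz) in ((r1, m1, e1), (r2, m2, e2)):
                h = config.growth_heritability
                mu = config.base_elongation_rate + h * (cell.elongation_rate
                     - config.base_elongation_rate)
                beta = max(float(rng.normal(
                    mu, config.growth_noise_sd * math.sqrt(1 - h * h))), 1e-4)
                dl = 2.0 * config.mean_birth_length_um \
                    * math.exp(rng.normal(0.0, config.division_cv))
                d = CellState(
                    cell_id=id_counter[0], lineage_id=cell.lineage_id,
                    parent_id=cell.cell_id, genotype=cell.genotype,
                    length=half, elongation_rate=beta,
                    enzyme_level=enz, reporter=rep, marker=mar,
                    internal_h2o2=cell.internal_h2o2, alive=True,
                    birth_length=half, division_length=dl,
                    excess_time=0.0,
                    sensed_history=list(cell.sensed_history),
                )
                id_counter[0] += 1
                daughters.append(d)
            out.extend(daughters)
        else:
            out.append(cell)
    # restack from the closed end; a cell protruding past the opening is
    # swept away by the flow channel
    pos = 0.0
    kept: list[CellState] = []
    for cell in out:
        if pos + cell.length > config.trench_length_um:
            break
        cell.position = pos
        pos += cell.length
        kept.append(cell)
    return kept


# ---------------------------------------------------------------------------
# vectorised engine
# ---------------------------------------------------------------------------

class _Trench:
    """Array-of-attributes state for one trench (index 0 = closed end)."""

    __slots__ = ("cfg", "rng", "meas_rng", "n", "L", "birth_L", "div_L", "beta",
                 "E", "R", "M", "cint", "geno", "alive", "excess", "cell_id",
                 "parent_id", "lineage_id", "recorded", "hist", "hist_ptr",
                 "next_id", "sigma", "delay_e", "delay_r", "exited", "died",
                 "length_um")

    def __init__(self, cfg: SimConfig, rng: np.random.Generator,
                 meas_rng: np.random.Generator, id_base: int = 0):
        self.cfg = cfg
        self.rng = rng
        self.meas_rng = meas_rng
        self.sigma = effective_sigma(cfg)
        # per-trench effective length (fabrication variability)
        self.length_um = float(np.clip(
            rng.normal(cfg.trench_length_um, cfg.trench_length_sd_um),
            0.6 * cfg.trench_length_um, 1.4 * cfg.trench_length_um))
        self.delay_e = int(round(cfg.enzyme.delay_min / cfg.substep_min))
        self.delay_r = int(round(cfg.reporter.delay_min / cfg.substep_min))
        self.exited = 0
        self.died = 0
        n = int(np.clip(rng.poisson(cfg.loading_mean_cells), 1,
                        max(int(cfg.trench_length_um / cfg.mean_birth_length_um), 1)))
        genos = list(cfg.genotype_mix.keys())
        probs = np.array([cfg.genotype_mix[g] for g in genos], dtype=float)
        probs = probs / probs.sum()
        pick = rng.choice(len(genos), size=n, p=probs)
        self.geno = np.array([_GENO_CODE[genos[i]] for i in pick], dtype=np.int8)
        # lengths drawn uniform in log between birth and division size
        b = cfg.mean_birth_length_um
        self.L = b * np.exp(rng.uniform(0.0, math.log(2.0), n))
        self.birth_L = np.full(n, b)
        self.div_L = 2.0 * b * np.exp(rng.normal(0.0, cfg.division_cv, n))
        # trim the loaded stack so it fits inside the trench
        inside = np.cumsum(self.L) <= self.length_um
        inside[0] = True
        n = int(inside.sum())
        for name in ("geno", "L", "birth_L", "div_L"):
            setattr(self, name, getattr(self, name)[inside])

        self.beta = np.maximum(rng.normal(cfg.base_elongation_rate,
                                          cfg.growth_noise_sd, n), 1e-4)
        self.beta[self.geno == _GENO_CODE["inert"]] = 0.0
        self.E = np.full(n, cfg.enzyme.basal_level)
        self.E[self.geno == _GENO_CODE["inert"]] = 0.0
        area = cfg.trench_width_um * self.L
        self.R = (cfg.reporter.basal_rate / cfg.base_elongation_rate) * area
        self.M = (cfg.marker_rate / cfg.base_elongation_rate) * area
        self.cint = np.zeros(n)
        self.alive = np.ones(n, dtype=bool)
        self.alive[self.geno == _GENO_CODE["inert"]] = True  # inert: static mass
        self.excess = np.zeros(n)
        self.cell_id = id_base + np.arange(1, n + 1, dtype=np.int64)
        self.parent_id = np.full(n, -1, dtype=np.int64)
        self.lineage_id = self.cell_id.copy()
        self.recorded = np.zeros(n, dtype=bool)
        self.next_id = id_base + n + 1
        self.n = n
        H = max(self.delay_e, self.delay_r) + 1
        self.hist = np.zeros((n, H))
        self.hist_ptr = 0

    # -- helpers ---------------------------------------------------------
    def _scavenging(self) -> np.ndarray:
        e = np.where(self.alive, self.E, 0.0)
        e[self.geno == _GENO_CODE["inert"]] = 0.0
        return e

    def _local_conc(self, c0: float) -> np.ndarray:
        e = self._scavenging()
        if self.cfg.attenuation_mode == "fixed":
            f = np.where(e > 0, self.cfg.fixed_attenuation, 0.0)
            log_keep = np.log1p(-f)
        else:
            s = surface_area(self.L, self.cfg.trench_width_um)
            log_keep = -self.sigma * s * e
        # barriers of cell i are all cells j > i (closer to the open end)
        rev = log_keep[::-1]
        shield = np.cumsum(rev)[::-1] - log_keep  # sum over j > i
        return c0 * np.exp(shield)

    def substep(self, c0: float, dt: float) -> None:
        cfg = self.cfg
        c_loc = self._local_conc(c0)
        e_self = self._scavenging()
        target = c_loc / (1.0 + cfg.internal_scavenging_strength * e_self)
        decay = math.exp(-cfg.internal_relaxation_rate * dt)
        self.cint = target + (self.cint - target) * decay
        # delayed sensing via ring buffer of past internal concentrations
        H = self.hist.shape[1]
        self.hist[:, self.hist_ptr] = self.cint
        sensed_e = self.hist[:, (self.hist_ptr - self.delay_e) % H]
        sensed_r = self.hist[:, (self.hist_ptr - self.delay_r) % H]
        self.hist_ptr = (self.hist_ptr + 1) % H
        g = _growth_factor(self.cint, cfg)
        dmg = _damage_factor(self.cint, cfg)
        wt = (self.geno == _GENO_CODE["WT"]) & self.alive
        live = (self.geno != _GENO_CODE["inert"]) & self.alive
        # enzyme induction (WT only), dilution by growth
        h_e = hill(sensed_e, cfg.enzyme.hill_k_uM, cfg.enzyme.hill_n)
        dE = cfg.enzyme.max_rate * h_e * (1.0 - self.E) * dmg - self.beta * g * self.E
        self.E = np.where(wt, np.clip(self.E + dE * dt, cfg.enzyme.basal_level, 1.0),
                          self.E)
        # reporter / marker production proportional to area
        area = cfg.trench_width_um * self.L
        h_r = hill(sensed_r, cfg.reporter.hill_k_uM, cfg.reporter.hill_n)
        prod = np.where(wt, cfg.reporter.basal_rate + cfg.reporter.max_induced_rate * h_r,
                        cfg.reporter.basal_rate)
        self.R = self.R + np.where(live, prod * dmg * area * dt, 0.0)
        self.M = self.M + np.where(live, cfg.marker_rate * dmg * area * dt, 0.0)
        # growth
        self.L = np.where(live, self.L * np.exp(self.beta * g * dt), self.L)
        # death rule
        tol = cfg.death.lethal_uM + cfg.death.priming_coefficient_uM * self.E
        over = live & (self.cint > tol)
        self.excess = np.where(over, self.excess + dt, 0.0)
        dying = live & (self.excess >= cfg.death.sustained_min)
        if dying.any():
            self.died += int(dying.sum())
            self.alive &= ~dying
            self.beta = np.where(dying, 0.0, self.beta)
        # divisions: stressed cells divide at smaller sizes (threshold
        # scales with g^q, mirroring growth-rate-dependent cell size)
        thresh = self.div_L * np.clip(g, 0.3, 1.0) ** cfg.stress_size_exponent
        ready = live & ~dying & (self.L >= thresh)
        if ready.any():
            self._divide(np.nonzero(ready)[0])
        # exits: a cell protruding past the opening is swept by the flow
        ends = np.cumsum(self.L)
        keep = ends <= self.length_um
        if not keep.all():
            self.exited += int((~keep).sum())
            self._select(keep)
        if not np.isfinite(self.L).all() or not np.isfinite(self.R).all():
            raise SimulationError("non-finite cell state")

    def _select(self, keep: np.ndarray) -> None:
        for name in ("L", "birth_L", "div_L", "beta", "E", "R", "M", "cint",
                     "geno", "alive", "excess", "cell_id", "parent_id",
                     "lineage_id", "recorded"):
            setattr(self, name, getattr(self, name)[keep])
        self.hist = self.hist[keep]
        self.n = int(self.L.size)

    def _divide(self, idx: np.ndarray) -> None:
        cfg = self.cfg
        rng = self.rng
        pieces: dict[str, list] = {k: [] for k in
                                   ("L", "birth_L", "div_L", "beta", "E", "R",
                                    "M", "cint", "geno", "alive", "excess",
                                    "cell_id", "parent_id", "lineage_id",
                                    "recorded")}
        hist_rows: list[np.ndarray] = []
        divset = set(int(i) for i in idx)
        for i in range(self.n):
            if i not in divset:
                for k in pieces:
                    pieces[k].append(np.atleast_1d(getattr(self, k)[i]))
                hist_rows.append(self.hist[i:i + 1])
                continue
            half = self.L[i] / 2.0
            p = float(np.clip(rng.normal(0.5, cfg.partition_noise_sd), 0.3, 0.7))
            pe = float(np.clip(rng.normal(0.5, cfg.partition_noise_sd), 0.3, 0.7))
            pm = float(np.clip(rng.normal(0.5, cfg.partition_noise_sd), 0.3, 0.7))
            h = cfg.growth_heritability
            mu = cfg.base_elongation_rate + h * (self.beta[i]
                                                 - cfg.base_elongation_rate)
            betas = np.maximum(rng.normal(
                mu, cfg.growth_noise_sd * math.sqrt(1.0 - h * h), 2), 1e-4)
            divls = 2.0 * cfg.mean_birth_length_um \
                * np.exp(rng.normal(0.0, cfg.division_cv, 2))
            ids = np.array([self.next_id, self.next_id + 1], dtype=np.int64)
            self.next_id += 2
            pieces["L"].append(np.array([half, half]))
            pieces["birth_L"].append(np.array([half, half]))
            pieces["div_L"].append(divls)
            pieces["beta"].append(betas)
            pieces["E"].append(np.clip(np.array([2.0 * pe, 2.0 * (1 - pe)])
                                       * self.E[i], 0.0, 1.0))
            pieces["R"].append(np.array([p, 1 - p]) * self.R[i])
            pieces["M"].append(np.array([pm, 1 - pm]) * self.M[i])
            pieces["cint"].append(np.array([self.cint[i]] * 2))
            pieces["geno"].append(np.array([self.geno[i]] * 2, dtype=np.int8))
            pieces["alive"].append(np.array([True, True]))
            pieces["excess"].append(np.zeros(2))
            pieces["cell_id"].append(ids)
            # an unrecorded parent (born and divided within one frame) would
            # dangle in the output; link to its last recorded ancestor
            pid = self.cell_id[i] if self.recorded[i] else self.parent_id[i]
            pieces["parent_id"].append(np.array([pid] * 2, dtype=np.int64))
            pieces["lineage_id"].append(np.array([self.lineage_id[i]] * 2,
                                                 dtype=np.int64))
            pieces["recorded"].append(np.array([False, False]))
            hist_rows.append(np.repeat(self.hist[i:i + 1], 2, axis=0))
        for k, vals in pieces.items():
            setattr(self, k, np.concatenate(vals))
        self.hist = np.concatenate(hist_rows, axis=0)
        self.n = int(self.L.size)

    def record(self, trench_id: int, frame: int, t: float, c0: float,
               dt_frame: float) -> dict:
        cfg = self.cfg
        self.recorded[:] = True
        area = cfg.trench_width_um * self.L
        noise_r = self.meas_rng.normal(0.0, cfg.measurement_noise_sd, self.n)
        noise_m = self.meas_rng.normal(0.0, cfg.measurement_noise_sd, self.n)
        lam = cfg.mismatch.basal + cfg.mismatch.induced_per_uM \
            * np.maximum(self.cint, 0.0) * (1.0 - self.E)
        live = (self.geno != _GENO_CODE["inert"]) & self.alive
        foci = np.where(live, self.meas_rng.poisson(lam * dt_frame), 0)
        starts = np.concatenate(([0.0], np.cumsum(self.L)[:-1]))
        return {
            "trench_id": np.full(self.n, trench_id, dtype=np.int32),
            "frame": np.full(self.n, frame, dtype=np.int32),
            "time_min": np.full(self.n, t),
            "cell_index": np.arange(self.n, dtype=np.int16),
            "cell_id": self.cell_id.copy(),
            "lineage_id": self.lineage_id.copy(),
            "parent_id": self.parent_id.copy(),
            "genotype": self.geno.copy(),
            "length_um": self.L.copy(),
            "area_um2": area,
            "position_um": starts,
            "reporter_au": self.R / area + noise_r,
            "marker_au": self.M / area + noise_m,
            "foci_count": foci.astype(np.int32),
            "alive": self.alive.copy(),
            "external_c0_uM": np.full(self.n, c0),
        }


def simulate(config: SimConfig, schedule: TreatmentSchedule,
             progress: bool = False):
    """Run the trench simulator and return ``(tracks, meta)``.

    ``tracks`` is a long-format DataFrame with one row per live cell per
    frame (columns :data:`TRACK_COLUMNS`); ``meta`` records the seed, config
    digest and exit/death counts.  The run is deterministic given
    ``(config, schedule, config.seed)``: each trench evolves under its own
    child RNG stream, so individual trenches do not change when
    ``n_trenches`` does.
    """
    cfg = config
    cfg.validate()
    n_sub = int(round(cfg.frame_interval_min / cfg.substep_min))
    frames = int(round((cfg.t_end_min - cfg.t_start_min) / cfg.frame_interval_min)) + 1
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_trenches)
    chunks: list[dict] = []
    exited = died = 0
    for ti in range(cfg.n_trenches):
        dyn_ss, meas_ss = children[ti].spawn(2)
        trench = _Trench(cfg, np.random.default_rng(dyn_ss),
                         np.random.default_rng(meas_ss),
                         id_base=(ti + 1) * 10_000_000)
        t = cfg.t_start_min
        for frame in range(frames):
            c0 = schedule.concentration(t)
            chunks.append(trench.record(ti, frame, t, c0, cfg.frame_interval_min))
            if frame == frames - 1:
                break
            for k in range(n_sub):
                tau = t + k * cfg.substep_min
                trench.substep(schedule.concentration(tau), cfg.substep_min)
            t = cfg.t_start_min + (frame + 1) * cfg.frame_interval_min
        exited += trench.exited
        died += trench.died
    data = {k: np.concatenate([c[k] for c in chunks]) for k in chunks[0]}
    df = pd.DataFrame(data)
    df["genotype"] = pd.Categorical.from_codes(df["genotype"],
                                               categories=[_GENO_NAME[i] for i in range(3)])
    df = df[TRACK_COLUMNS]
    meta = {
        "schema_version": "1",
        "seed": cfg.seed,
        "config_digest": config_digest(cfg, schedule),
        "frame_interval_min": cfg.frame_interval_min,
        "t_start_min": cfg.t_start_min,
        "n_trenches": cfg.n_trenches,
        "exited": exited,
        "died": died,
    }
    return df, meta
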