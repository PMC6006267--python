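"""A 3D leaky integrate-and-fire reservoir with small-world wiring.

The reservoir places N neurons (default 732) at 3D coordinates shaped
like the primary visual cortex and wires them with the "small-world"
rule: each ordered pair within a maximum distance ``d_max`` is
connected with probability ``p_connect``, with initial magnitudes
inversely proportional to distance.  Neurons are excitatory with
probability 0.8 and, by default, all outgoing synapses of a neuron
share its sign (Dale-consistent); a flag restores fully independent
per-connection signs.

The 128 encoder channels are mapped onto distinct reservoir neurons
retinotopically: foveal channels into the posterior half of the cloud
(cortical magnification: half of V1 serves the fovea), peripheral
channels into the anterior half, with the visual field flipped and
mirrored in the plane orthogonal to the posterior-anterior axis.

Unsupervised learning is pair-based STDP: additive potentiation for
causal pre-before-post pairs, multiplicative depression for
anti-causal pairs, with exponential decay in the pair lag.  Silent
synapses between neurons within twice the wiring radius may be grown
by a first causal pairing, which lets training bridge gaps the
small-world initialization cannot cross.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .retina import GROUP_SLICES, RetinaMap, SpikeRaster

__all__ = [
    "NeuronCoordinates",
    "ReservoirConfig",
    "STDPConfig",
    "Reservoir",
    "init_reservoir",
    "map_inputs_retinotopic",
    "step",
    "run_unsupervised",
    "propagate_and_record",
    "connectivity_snapshot",
    "save_snapshot",
]

logger = logging.getLogger(__name__)

_NEVER = -(2**31)  # sentinel last-spike bin: no spike yet


@dataclass
class NeuronCoordinates:
    """N x 3 neuron positions; ``anterior_axis`` points posterior -> anterior."""

    positions: np.ndarray
    anterior_axis: int = 1

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if self.anterior_axis not in (0, 1, 2):
            raise ValueError("anterior_axis must be 0, 1 or 2")
        uniq = np.unique(self.positions, axis=0)
        if len(uniq) != len(self.positions):
            raise ValueError("duplicate neuron positions")

    @property
    def n(self) -> int:
        return len(self.positions)

    @classmethod
    def from_csv(cls, path, anterior_axis: int = 1) -> "NeuronCoordinates":
        df = pd.read_csv(path)
        return cls(df[["x", "y", "z"]].to_numpy(float), anterior_axis)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.positions, columns=["x", "y", "z"]).to_csv(
            path, index=False, float_format="%.6f"
        )


@dataclass(frozen=True)
class ReservoirConfig:
    """LIF and wiring parameters.

    ``fire_threshold``, ``refractory_bins`` and ``leak_rate`` default to
    0.5, 6 and 0.002; ``d_max`` (wiring radius) to 2.5 in coordinate
    units; 80% of neurons are excitatory.
    """

    fire_threshold: float = 0.5
    refractory_bins: int = 6
    leak_rate: float = 0.002
    d_max: float = 2.5
    p_connect: float = 0.15
    excitatory_fraction: float = 0.8
    w_init_scale: float = 0.2
    per_connection_signs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.leak_rate < 1.0:
            raise ValueError("leak_rate must be in [0, 1)")
        if not 0.0 < self.excitatory_fraction < 1.0:
            raise ValueError("excitatory_fraction must be in (0, 1)")
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")


@dataclass(frozen=True)
class STDPConfig:
    """Pair-based STDP parameters (learning rate 0.01 by default)."""

    rate: float = 0.01
    tau_bins: float = 2.0
    window_bins: int = 6
    w_max: float = 1.0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.tau_bins <= 0:
            raise ValueError("tau_bins must be positive")


class Reservoir:
    """Wired LIF reservoir with mutable weights and simulation state."""

    def __init__(
        self,
        coords: NeuronCoordinates,
        config: ReservoirConfig,
        w_mag: np.ndarray,
        sign: np.ndarray,
        excitatory: np.ndarray,
        distances: np.ndarray,
    ):
        self.coords = coords
        self.config = config
        self.w_mag = w_mag  # synapse magnitudes >= 0; 0 = absent
        self.sign = sign  # per-pair sign (int8), rows = presynaptic
        self.excitatory = excitatory
        self.distances = distances
        self.growth_mask = distances <= 2.0 * config.d_max
        np.fill_diagonal(self.growth_mask, False)
        self.input_assignment: np.ndarray | None = None
        self.reset_state()

    @property
    def n(self) -> int:
        return self.coords.n

    @property
    def weights(self) -> np.ndarray:
        """Signed synapse matrix (presynaptic rows, postsynaptic columns)."""
        return self.sign * self.w_mag

    def reset_state(self) -> None:
        self.potential = np.zeros(self.n)
        self.refractory = np.zeros(self.n, dtype=np.int64)
        self.prev_spikes = np.zeros(self.n, dtype=bool)

    def step(self, input_spikes: np.ndarray) -> np.ndarray:
        """Advance one time bin; returns the boolean spike vector.

        Refractory neurons only count down.  Others leak, integrate
        last bin's reservoir spikes through the weights, and receive a
        threshold-sized injection on their assigned input channel's
        spike (input spikes force the assigned neuron to fire).
        """
        cfg = self.config
        in_refr = self.refractory > 0
        active = np.flatnonzero(self.prev_spikes)
        drive = np.zeros(self.n)
        if active.size:
            drive = (self.sign[active] * self.w_mag[active]).sum(axis=0)
        if self.input_assignment is not None:
            input_spikes = np.asarray(input_spikes, dtype=bool)
            drive[self.input_assignment[input_spikes]] += cfg.fire_threshold
        elif np.any(input_spikes):
            raise ValueError("input spikes given but no input assignment is set")
        v = self.potential * (1.0 - cfg.leak_rate) + drive
        v[in_refr] = self.potential[in_refr]  # refractory: frozen, input ignored
        spikes = (~in_refr) & (v >= cfg.fire_threshold)
        v[spikes] = 0.0
        refr = self.refractory - in_refr.astype(np.int64)
        refr[spikes] = cfg.refractory_bins
        self.potential = v
        self.refractory = refr
        self.prev_spikes = spikes
        return spikes


def init_reservoir(coords: NeuronCoordinates, config: ReservoirConfig) -> Reservoir:
    """Small-world initialization, fully determined by ``config.seed``.

    Each ordered pair (i, j), i != j, with distance <= d_max is
    connected with probability ``p_connect``; magnitudes are drawn
    Uniform(0, w_init_scale) / distance.
    """
    n = coords.n
    if n < 2:
        raise ValueError("reservoir needs at least 2 neurons")
    dist = cdist(coords.positions, coords.positions)
    rng = np.random.default_rng(config.seed)
    in_range = dist <= config.d_max
    np.fill_diagonal(in_range, False)
    connected = in_range & (rng.random((n, n)) < config.p_connect)
    draws = rng.uniform(0.0, config.w_init_scale, (n, n))
    w_mag = np.zeros((n, n))
    w_mag[connected] = draws[connected] / dist[connected]
    excitatory = rng.random(n) < config.excitatory_fraction
    sign = np.where(excitatory, 1, -1).astype(np.int8)[:, None].repeat(n, axis=1)
    if config.per_connection_signs:
        per_conn = np.where(
            rng.random(int(connected.sum())) < config.excitatory_fraction, 1, -1
        ).astype(np.int8)
        sign[connected] = per_conn
    return Reservoir(coords, config, w_mag, sign, excitatory, dist)


def map_inputs_retinotopic(coords: NeuronCoordinates, rmap: RetinaMap) -> np.ndarray:
    """Deterministically assign the 128 channels to reservoir neurons.

    The 64 foveal channels go to the most-posterior half of the cloud
    and the 64 pooled-group channels to the anterior half, so exactly
    50% of input neurons carry foveal signal.  Within each half, a
    channel's receptive-field center is negated (the retinal image is
    flipped and mirrored on its way to V1), scaled into the half's
    extent in the plane orthogonal to the anterior axis, and matched
    greedily to the nearest unused neuron in order of increasing
    eccentricity.  Returns an injective length-128 neuron-index array
    in canonical channel order.
    """
    n = coords.n
    if n < rmap.n_cells:
        raise ValueError(f"need >= {rmap.n_cells} neurons, got {n}")
    ant_axis = coords.anterior_axis
    plane_axes = [a for a in (0, 1, 2) if a != ant_axis]
    order = np.argsort(coords.positions[:, ant_axis], kind="stable")
    halves = {"posterior": order[: n // 2], "anterior": order[n // 2 :]}

    centers = np.array([f.center for f in rmap.fields])
    rel = centers - np.array([rmap.width / 2.0, rmap.height / 2.0])
    target = -rel  # flip + mirror
    ecc = np.hypot(rel[:, 0], rel[:, 1])

    fovea_ch = np.arange(*GROUP_SLICES["fovea"].indices(rmap.n_cells))
    group_ch = np.arange(0, GROUP_SLICES["fovea"].start)
    assignment = np.full(rmap.n_cells, -1, dtype=np.int64)
    half_extent = max(rmap.width, rmap.height) / 2.0
    for channels, pool in ((fovea_ch, halves["posterior"]), (group_ch, halves["anterior"])):
        pts = coords.positions[np.ix_(pool, plane_axes)]
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        scaled = lo + (target[channels] + half_extent) / (2 * half_extent) * (hi - lo)
        used = np.zeros(len(pool), dtype=bool)
        for k in np.argsort(ecc[channels], kind="stable"):
            d2 = ((pts - scaled[k]) ** 2).sum(axis=1)
            d2[used] = np.inf
            pick = int(np.argmin(d2))
            used[pick] = True
            assignment[channels[k]] = pool[pick]
    return assignment


def step(reservoir: Reservoir, input_spikes: np.ndarray, bin_index: int | None = None):
    """Functional wrapper around :meth:`Reservoir.step`."""
    return reservoir.step(input_spikes)


def _stdp_update(
    res: Reservoir,
    spikes: np.ndarray,
    last_spike: np.ndarray,
    t: int,
    stdp: STDPConfig,
) -> None:
    """Apply pair-based STDP for the spikes emitted at bin ``t``.

    Pairing is nearest-neighbor: each neuron's most recent earlier
    spike within ``window_bins`` pairs with the current spike.  For a
    causal pair i (earlier) -> j (now): |w_ij| += rate * exp(-dt/tau),
    growing a silent eligible synapse at |w| = rate on its first such
    pairing.  For an anti-causal pair: |w| *= 1 - rate * exp(-dt/tau).
    Magnitudes are clipped to [0, w_max]; signs never change.
    """
    now = np.flatnonzero(spikes)
    if now.size == 0:
        return
    dt = t - last_spike
    paired = np.flatnonzero((dt >= 1) & (dt <= stdp.window_bins))
    if paired.size == 0:
        return
    decay = np.exp(-dt[paired] / stdp.tau_bins)
    # Potentiation: earlier presynaptic spike -> current postsynaptic spike.
    ix = np.ix_(paired, now)
    sub = res.w_mag[ix]
    eligible_new = res.growth_mask[ix] & (sub == 0.0)
    sub = sub + (sub > 0.0) * (stdp.rate * decay[:, None])
    sub[eligible_new] = stdp.rate
    res.w_mag[ix] = np.clip(sub, 0.0, stdp.w_max)
    # Depression: current presynaptic spike, earlier postsynaptic spike.
    ix = np.ix_(now, paired)
    res.w_mag[ix] = np.clip(
        res.w_mag[ix] * (1.0 - stdp.rate * decay[None, :]), 0.0, stdp.w_max
    )


def propagate_and_record(
    reservoir: Reservoir,
    raster: SpikeRaster,
    plastic: bool = False,
    stdp: STDPConfig | None = None,
) -> np.ndarray:
    """Drive the reservoir with an input raster from a reset state.

    Returns the full (N x T) boolean reservoir spike record.  With
    ``plastic=True`` STDP modifies the weights while the sample plays.
    """
    if raster.n_cells != 128:
        raise ValueError(f"input raster must have 128 cells, got {raster.n_cells}")
    if reservoir.input_assignment is None:
        raise ValueError("reservoir has no input assignment; map inputs first")
    if plastic and stdp is None:
        stdp = STDPConfig()
    reservoir.reset_state()
    T = raster.n_bins
    record = np.zeros((reservoir.n, T), dtype=bool)
    last_spike = np.full(reservoir.n, _NEVER, dtype=np.int64)
    for t in range(T):
        spikes = reservoir.step(raster.spikes[:, t])
        record[:, t] = spikes
        if plastic:
            _stdp_update(reservoir, spikes, last_spike, t, stdp)
        last_spike[spikes] = t
    return record


def run_unsupervised(
    reservoir: Reservoir, rasters: list[SpikeRaster], stdp: STDPConfig
) -> Reservoir:
    """Train the reservoir with STDP on each raster in turn.

    State (but not weights) is reset between samples; the reservoir is
    mutated and returned.
    """
    if not rasters:
        raise ValueError("no rasters to train on")
    for raster in rasters:
        propagate_and_record(reservoir, raster, plastic=True, stdp=stdp)
    return reservoir


def connectivity_snapshot(reservoir: Reservoir) -> pd.DataFrame:
    """Edge table (i, j, weight, sign, distance) of all live synapses."""
    i, j = np.nonzero(reservoir.w_mag)
    sign = reservoir.sign[i, j].astype(int)
    df = pd.DataFrame(
        {
            "i": i,
            "j": j,
            "weight": sign * reservoir.w_mag[i, j],
            "sign": sign,
            "distance": reservoir.distances[i, j],
        }
    )
    df.attrs["n_positive"] = int((sign > 0).sum())
    df.attrs["n_negative"] = int((sign < 0).sum())
    return df


def save_snapshot(snapshot: pd.DataFrame, csv_path=None, graphml_path=None) -> None:
    """Serialize an edge table to CSV and/or GraphML."""
    if csv_path is not None:
        snapshot.to_csv(csv_path, index=False, float_format="%.8g")
    if graphml_path is not None:
        import networkx as nx

        g = nx.DiGraph()
        for row in snapshot.itertuples(index=False):
            g.add_edge(
                int(row.i),
                int(row.j),
                weight=float(row.weight),
                sign=int(row.sign),
                distance=float(row.distance),
            )
        nx.write_graphml(g, graphml_path)
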