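"""NCD-based construction of a layered M1 column network description.

The column is a cylinder (300 um diameter, 1350 um depth by default) with
cells placed uniformly within per-layer normalized-cortical-depth (NCD)
bands at configured per-layer densities.  Wiring follows the
scon = pcon x vcon disentanglement: a connection-strength grid (scon, mV)
and a unitary-EPSP grid (vcon, mV, thresholded to [0.3, 1.0] mV) give the
base connection probability pcon = scon / vcon; probability then decays
exponentially with inter-somatic distance (length constant 100 um) with a
border correction that renormalises the lateral kernel mass inside the
cylinder.  Delays are 2 ms plus distance at 0.5 m/s propagation.  Unitary
weights are divided over 5 synapses for morphologically detailed targets
(IT5A, PT5B) or 1 otherwise and split across receptors (50/50 AMPA/NMDA for
excitatory; 90/10 slow-GABAA/GABAB for SOM onto excitatory cells; 100% fast
GABAA for PV).  Class-specific adjustments (CT input scaling, L4<->L2/3
asymmetry, PV/SOM biases, same-layer restriction of inhibition) are applied
exactly once.

The quantitative scon/vcon source grids are not public; the defaults here
are editable placeholders at a realistic scale with a documented schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ColumnGeometry",
    "ConnectionRule",
    "RuleSet",
    "NetworkConfig",
    "NetworkSpec",
    "SYNAPSE_PARAMS",
    "DETAILED_POPULATIONS",
    "cylinder_volume",
    "place_cells",
    "pcon_from_scon",
    "threshold_vcon",
    "lateral_prob",
    "border_correction_factor",
    "conduction_delay",
    "nmda_factor",
    "split_unitary_weight",
    "apply_class_adjustments",
    "build_network",
    "export_network",
    "import_network",
]

VCON_MIN, VCON_MAX = 0.3, 1.0  # mV, unitary-EPSP thresholding
LATERAL_DECAY_UM = 100.0
DELAY_BASE_MS = 2.0
PROPAGATION_M_PER_S = 0.5
NMDA_COEFFS = (0.28, 0.062)
DETAILED_POPULATIONS = frozenset({"IT5A", "PT5B"})

# receptor -> (rise ms, decay ms, reversal mV); the GABAB entry stands in
# for the G-protein/GIRK cascade, whose kinetics are outside this package's
# scope, with a slow double-exponential at the GABAB reversal.
SYNAPSE_PARAMS: dict[str, tuple[float, float, float]] = {
    "AMPA": (0.05, 5.3, 0.0),
    "NMDA": (15.0, 150.0, 0.0),
    "GABAA_fast": (0.07, 18.2, -80.0),
    "GABAA_slow": (2.0, 100.0, -80.0),
    "GABAB": (3.5, 260.0, -95.0),
}

EXCITATORY_LAYER_BANDS = {
    "L2/3": (0.10, 0.29),
    "L4": (0.29, 0.37),
    "L5A": (0.37, 0.47),
    "L5B": (0.47, 0.80),
    "L6": (0.80, 1.00),
}
# interneuron scheme uses slightly different subdivisions
INTERNEURON_LAYER_BANDS = {
    "L2/3": (0.12, 0.31),
    "L4/5A/5B": (0.31, 0.77),
    "L6": (0.77, 1.00),
}

# layers 4, 5A and 5B count as one layer for same-layer inhibition
MERGED_LAYER = {
    "L2/3": "L2/3",
    "L4": "L4/5A/5B",
    "L4/5A": "L4/5A/5B",
    "L5A": "L4/5A/5B",
    "L5B": "L4/5A/5B",
    "L6": "L6",
}

DEFAULT_DENSITIES = {  # cells per mm^3
    "L2/3": 138_900.0,
    "L4": 105_600.0,
    "L5A": 126_700.0,
    "L5B": 96_000.0,
    "L6": 131_900.0,
}

# per layer: (excitatory population shares, inhibitory population shares)
DEFAULT_COMPOSITION: dict[str, tuple[dict[str, float], dict[str, float]]] = {
    "L2/3": ({"IT2/3": 1.0}, {"PV2/3": 2 / 3, "SOM2/3": 1 / 3}),
    "L4": ({"IT4": 1.0}, {"PV5A": 2 / 3, "SOM5A": 1 / 3}),
    "L5A": ({"IT5A": 1.0}, {"PV5A": 2 / 3, "SOM5A": 1 / 3}),
    "L5B": ({"IT5B": 0.5, "PT5B": 0.5}, {"PV5B": 2 / 3, "SOM5B": 1 / 3}),
    "L6": ({"IT6": 0.5, "CT6": 0.5}, {"PV6": 2 / 3, "SOM6": 1 / 3}),
}
DEFAULT_E_FRACTION = 0.8


class AdjustmentError(RuntimeError):
    """Class adjustments were applied more than once."""


@dataclass
class ColumnGeometry:
    diameter_um: float = 300.0
    depth_um: float = 1350.0
    layer_bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(EXCITATORY_LAYER_BANDS)
    )

    def __post_init__(self) -> None:
        for layer, (lo, hi) in self.layer_bands.items():
            if not 0.0 <= lo < hi <= 1.0:
                raise ValueError(f"bad NCD band for {layer}: ({lo}, {hi})")

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0

    def volume_um3(self) -> float:
        return cylinder_volume(self.diameter_um, self.depth_um)


@dataclass
class ConnectionRule:
    """Wiring rule for one (pre population, post population) pair."""

    pre: str
    post: str
    scon: float  # connection strength, mV
    vcon_raw: float  # unitary EPSP before thresholding, mV
    decay_um: float = LATERAL_DECAY_UM
    pcon_scale: float = 1.0  # multiplicative class adjustment on pcon
    same_layer_only: bool = False

    @property
    def vcon(self) -> float:
        return threshold_vcon(self.vcon_raw)

    @property
    def pcon(self) -> float:
        return min(
            1.0, pcon_from_scon(self.scon, self.vcon) * self.pcon_scale
        )


@dataclass
class RuleSet:
    rules: dict[tuple[str, str], ConnectionRule]
    adjusted: bool = False

    def get(self, pre: str, post: str) -> ConnectionRule | None:
        return self.rules.get((pre, post))


@dataclass
class NetworkConfig:
    geometry: ColumnGeometry = field(default_factory=ColumnGeometry)
    densities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DENSITIES)
    )
    e_fraction: float = DEFAULT_E_FRACTION
    composition: dict = field(
        default_factory=lambda: {
            k: (dict(e), dict(i))
            for k, (e, i) in DEFAULT_COMPOSITION.items()
        }
    )
    rules: RuleSet | None = None  # None -> default placeholder grid
    apply_adjustments: bool = True
    border_correction: bool = True
    mg_mm: float = 1.0


@dataclass
class NetworkSpec:
    """Portable network description: geometry + node and edge tables."""

    geometry: ColumnGeometry
    neurons: pd.DataFrame  # id-indexed: population, layer, x, y, z, ncd, ei
    edges: pd.DataFrame  # pre_id, post_id, receptor weights, delay, ...

    @property
    def n_edges(self) -> int:
        return int(len(self.edges))


def cylinder_volume(diameter_um: float, depth_um: float) -> float:
    """Volume of a cylinder, um^3: pi * (d/2)^2 * depth."""
    if diameter_um < 0 or depth_um < 0:
        raise ValueError("diameter and depth must be non-negative")
    return float(np.pi * (diameter_um / 2.0) ** 2 * depth_um)


def _largest_remainder(total: int, shares: dict[str, float]) -> dict[str, int]:
    """Apportion ``total`` across keys proportionally to ``shares``."""
    if total == 0 or not shares:
        return {k: 0 for k in shares}
    norm = sum(shares.values())
    quotas = {k: total * v / norm for k, v in shares.items()}
    out = {k: int(np.floor(q)) for k, q in quotas.items()}
    leftover = total - sum(out.values())
    by_rem = sorted(
        shares, key=lambda k: (quotas[k] - out[k], k), reverse=True
    )
    for k in by_rem[:leftover]:
        out[k] += 1
    return out


def place_cells(
    geometry: ColumnGeometry,
    densities: dict[str, float],
    composition: dict | None = None,
    e_fraction: float = DEFAULT_E_FRACTION,
    seed: int = 0,
) -> pd.DataFrame:
    """Place neurons uniformly within each layer band of the cylinder.

    Per layer, ``count = round(density * layer_volume)``; the count is then
    apportioned to populations by the largest-remainder method using the
    excitatory fraction and the per-layer population shares (PV:SOM = 2:1,
    IT:PT = 1:1 in L5B, IT:CT = 1:1 in L6 by default).  Positions are
    uniform in the cylinder cross-section; NCD = z / depth.
    """
    if composition is None:
        composition = DEFAULT_COMPOSITION
    bands = geometry.layer_bands
    overlaps = sorted(bands.items(), key=lambda kv: kv[1][0])
    for (l1, b1), (l2, b2) in zip(overlaps, overlaps[1:]):
        if b2[0] < b1[1]:
            raise ValueError(f"layer bands {l1} and {l2} overlap")
    rng = np.random.default_rng(seed)
    area_mm2 = np.pi * (geometry.radius_um / 1000.0) ** 2
    rows = []
    next_id = 0
    for layer in sorted(bands):
        lo, hi = bands[layer]
        density = densities.get(layer, 0.0)
        thickness_mm = (hi - lo) * geometry.depth_um / 1000.0
        count = int(round(density * thickness_mm * area_mm2))
        if count == 0:
            continue
        e_shares, i_shares = composition[layer]
        ei_counts = _largest_remainder(
            count, {"excitatory": e_fraction, "inhibitory": 1 - e_fraction}
        )
        pop_counts: dict[str, int] = {}
        for pops, n in (
            (e_shares, ei_counts["excitatory"]),
            (i_shares, ei_counts["inhibitory"]),
        ):
            for label, c in _largest_remainder(n, pops).items():
                pop_counts[label] = pop_counts.get(label, 0) + c
        for label in sorted(pop_counts):
            n = pop_counts[label]
            r = geometry.radius_um * np.sqrt(rng.random(n))
            theta = rng.uniform(0, 2 * np.pi, n)
            z = rng.uniform(
                lo * geometry.depth_um, hi * geometry.depth_um, n
            )
            ei = (
                "inhibitory"
                if label.startswith(("PV", "SOM"))
                else "excitatory"
            )
            for k in range(n):
                rows.append(
                    (
                        next_id + k,
                        label,
                        layer,
                        r[k] * np.cos(theta[k]),
                        r[k] * np.sin(theta[k]),
                        z[k],
                        z[k] / geometry.depth_um,
                        ei,
                    )
                )
            next_id += n
    df = pd.DataFrame(
        rows, columns=["id", "population", "layer", "x", "y", "z", "ncd", "ei"]
    )
    return df.set_index("id")


def threshold_vcon(raw_mv: float) -> float:
    """Clamp a raw unitary-EPSP amplitude to [0.3, 1.0] mV."""
    if raw_mv < 0:
        raise ValueError("vcon must be non-negative")
    return float(np.clip(raw_mv, VCON_MIN, VCON_MAX))


def pcon_from_scon(scon_mv: float, vcon_mv: float) -> float:
    """pcon = scon / vcon, clipped to [0, 1] (a clip emits a warning)."""
    if vcon_mv <= 0:
        raise ValueError("vcon must be positive")
    p = scon_mv / vcon_mv
    if p > 1.0:
        import warnings

        warnings.warn(
            f"pcon = {p:.3f} > 1 clipped to 1 (scon={scon_mv}, "
            f"vcon={vcon_mv})",
            stacklevel=2,
        )
    return float(np.clip(p, 0.0, 1.0))


def lateral_prob(
    p0: float,
    distance_um: float,
    decay_um: float = LATERAL_DECAY_UM,
    border_correction: float = 1.0,
) -> float:
    """Connection probability after exponential lateral decay.

    ``p0 * exp(-d / decay) * border_correction``, clipped to [0, 1].
    """
    if decay_um <= 0:
        raise ValueError("decay constant must be positive")
    if distance_um < 0:
        raise ValueError("distance must be non-negative")
    return float(
        np.clip(p0 * np.exp(-distance_um / decay_um) * border_correction,
                0.0, 1.0)
    )


def border_correction_factor(
    r0_um: float | np.ndarray,
    radius_um: float,
    decay_um: float = LATERAL_DECAY_UM,
    n_phi: int = 256,
) -> np.ndarray:
    """Correction that restores the lateral kernel mass lost at the border.

    For a cell at lateral offset ``r0`` in a cylinder of radius ``R``, the
    factor is the ratio of the unbounded planar mass of exp(-d/lambda) to
    the mass inside the disc (numerically integrated), so cells near the
    edge do not receive systematically fewer or weaker connections.
    """
    r0 = np.atleast_1d(np.asarray(r0_um, dtype=float))
    if np.any(r0 > radius_um + 1e-9):
        raise ValueError("cell offset lies outside the cylinder")
    lam = decay_um
    phi = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
    out = np.empty(r0.shape)
    full = 2 * np.pi * lam * lam
    for i, r in enumerate(r0):
        s = np.sqrt(np.maximum(radius_um**2 - (r * np.sin(phi)) ** 2, 0.0))
        rho_max = -r * np.cos(phi) + s
        inner = lam * lam - np.exp(-rho_max / lam) * (
            lam * rho_max + lam * lam
        )
        mass = float(np.mean(inner) * 2 * np.pi)
        out[i] = full / mass
    return out if np.ndim(r0_um) else float(out[0])


def conduction_delay(distance_mm: float | np.ndarray) -> float | np.ndarray:
    """Delay in ms: 2 ms plus distance at 0.5 m/s propagation speed."""
    d = np.asarray(distance_mm, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    out = DELAY_BASE_MS + d / PROPAGATION_M_PER_S
    return float(out) if np.ndim(distance_mm) == 0 else out


def nmda_factor(v_mv: float | np.ndarray, mg_mm: float = 1.0):
    """Voltage-dependent NMDA conductance scaling.

    ``1 / (1 + 0.28 * Mg * exp(-0.062 * V))``; equals 1 for Mg = 0 and
    increases monotonically with V.
    """
    if mg_mm < 0:
        raise ValueError("Mg concentration must be non-negative")
    a, b = NMDA_COEFFS
    v = np.asarray(v_mv, dtype=float)
    out = 1.0 / (1.0 + a * mg_mm * np.exp(-b * v))
    return float(out) if np.ndim(v_mv) == 0 else out


def split_unitary_weight(
    vcon_mv: float,
    cell_detail: str,
    pre_class: str,
    post_ei: str = "excitatory",
) -> tuple[int, dict[str, float]]:
    """Per-synapse receptor weights and synapse count for one connection.

    ``cell_detail`` is that of the postsynaptic cell: ``"detailed"`` targets
    get 5 synapses per connection, ``"reduced"`` 1.  ``pre_class`` is
    ``"excitatory"``, ``"PV"`` or ``"SOM"``.  Excitatory weight splits 50/50
    AMPA/NMDA; SOM onto excitatory cells splits 90/10 slow-GABAA/GABAB, onto
    inhibitory cells 100% slow GABAA; PV is 100% fast GABAA.  Summed over
    synapses and receptors the weights reproduce vcon exactly.
    """
    if cell_detail == "detailed":
        n_syn = 5
    elif cell_detail == "reduced":
        n_syn = 1
    else:
        raise ValueError(f"unknown cell_detail {cell_detail!r}")
    per_syn = vcon_mv / n_syn
    if pre_class == "excitatory":
        weights = {"AMPA": 0.5 * per_syn, "NMDA": 0.5 * per_syn}
    elif pre_class == "PV":
        weights = {"GABAA_fast": per_syn}
    elif pre_class == "SOM":
        if post_ei == "excitatory":
            weights = {"GABAA_slow": 0.9 * per_syn, "GABAB": 0.1 * per_syn}
        else:
            weights = {"GABAA_slow": per_syn}
    else:
        raise ValueError(f"unknown pre_class {pre_class!r}")
    return n_syn, weights


def _pre_class(pop: str) -> str:
    if pop.startswith("PV"):
        return "PV"
    if pop.startswith("SOM"):
        return "SOM"
    return "excitatory"


def default_rules(populations: list[str]) -> RuleSet:
    """Placeholder scon/vcon grid: every pair gets a modest rule.

    The published source grids are not public; these editable defaults give
    excitatory rules scon 0.05 mV on vcon 0.5 mV (pcon 0.1 before decay)
    and inhibitory rules scon 0.1 mV on vcon 0.5 mV (pcon 0.2, same-layer).
    """
    rules = {}
    for pre in populations:
        for post in populations:
            inhibitory = _pre_class(pre) != "excitatory"
            rules[(pre, post)] = ConnectionRule(
                pre=pre,
                post=post,
                scon=0.10 if inhibitory else 0.05,
                vcon_raw=0.5,
                same_layer_only=inhibitory,
            )
    return RuleSet(rules=rules)


def apply_class_adjustments(
    ruleset: RuleSet, adjustments: list[dict] | None = None
) -> RuleSet:
    """Apply the class-specific wiring adjustments exactly once.

    Defaults: inputs to CT6 scaled to 62%; L2/3->L4 strength set to 1/4 of
    the (four times stronger) L4->L2/3 strength; L2/3 excitatory inputs to
    deep SOM cells +50% and to deep PV cells -50% in probability, with the
    opposite bias for deep IT inputs; inhibitory (PV/SOM) rules restricted
    to the same layer, with L4/5A/5B merged.  A second call raises.
    """
    if ruleset.adjusted:
        raise AdjustmentError("class adjustments already applied")
    if adjustments is None:
        adjustments = default_adjustments()
    for adj in adjustments:
        kind = adj["kind"]
        if kind == "scale_scon":
            for rule in ruleset.rules.values():
                if _match(rule, adj):
                    rule.scon *= adj["factor"]
        elif kind == "scale_pcon":
            for rule in ruleset.rules.values():
                if _match(rule, adj):
                    rule.pcon_scale *= adj["factor"]
        elif kind == "match_reverse_scaled":
            for (pre, post), rule in ruleset.rules.items():
                if _match(rule, adj):
                    reverse = ruleset.rules.get((post, pre))
                    if reverse is not None:
                        rule.scon = adj["factor"] * reverse.scon
        elif kind == "same_layer_inhibition":
            for rule in ruleset.rules.values():
                if _pre_class(rule.pre) != "excitatory":
                    rule.same_layer_only = True
        else:
            raise ValueError(f"unknown adjustment kind {kind!r}")
    ruleset.adjusted = True
    return ruleset


def _match(rule: ConnectionRule, adj: dict) -> bool:
    pre_sel = adj.get("pre")
    post_sel = adj.get("post")
    ok = True
    if pre_sel is not None:
        ok &= rule.pre in pre_sel
    if post_sel is not None:
        ok &= rule.post in post_sel
    return ok


DEEP_SOM = ("SOM5A", "SOM5B")
DEEP_PV = ("PV5A", "PV5B")
DEEP_IT = ("IT4", "IT5A", "IT5B")


def default_adjustments() -> list[dict]:
    return [
        {"kind": "scale_scon", "post": ("CT6",), "factor": 0.62},
        {
            "kind": "match_reverse_scaled",
            "pre": ("IT2/3",),
            "post": ("IT4",),
            "factor": 0.25,
        },
        {"kind": "scale_pcon", "pre": ("IT2/3",), "post": DEEP_SOM,
         "factor": 1.5},
        {"kind": "scale_pcon", "pre": ("IT2/3",), "post": DEEP_PV,
         "factor": 0.5},
        {"kind": "scale_pcon", "pre": DEEP_IT, "post": DEEP_PV,
         "factor": 1.5},
        {"kind": "scale_pcon", "pre": DEEP_IT, "post": DEEP_SOM,
         "factor": 0.5},
        {"kind": "same_layer_inhibition"},
    ]


def build_network(
    config: NetworkConfig, seed: int = 0, neurons: pd.DataFrame | None = None
) -> NetworkSpec:
    """Sample a full network: placement, Bernoulli edges, weights, delays.

    Deterministic under ``seed``.  Edge probability per (pre, post) pair is
    the rule's pcon decayed with 3-D inter-somatic distance and multiplied
    by the post cell's border-correction factor; no self-edges.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x4E7]))
    if neurons is None:
        neurons = place_cells(
            config.geometry,
            config.densities,
            config.composition,
            config.e_fraction,
            seed=seed,
        )
    ruleset = config.rules
    if ruleset is None:
        ruleset = default_rules(sorted(neurons["population"].unique()))
        if config.apply_adjustments:
            apply_class_adjustments(ruleset)
    pops = sorted(neurons["population"].unique())
    missing = [
        (a, b) for a in pops for b in pops if ruleset.get(a, b) is None
    ]
    if missing:
        raise ValueError(
            f"rule grid incomplete; missing {len(missing)} pairs, e.g. "
            f"{missing[:3]}"
        )
    pos = neurons[["x", "y", "z"]].to_numpy(dtype=float)
    ids = neurons.index.to_numpy()
    r_lat = np.hypot(pos[:, 0], pos[:, 1])
    # radial profile of the border correction, interpolated per cell
    if config.border_correction:
        grid = np.linspace(0.0, config.geometry.radius_um, 33)
        prof = border_correction_factor(grid, config.geometry.radius_um)
        corr = np.interp(r_lat, grid, prof)
    else:
        corr = np.ones(len(neurons))
    layer_of = neurons["layer"].map(MERGED_LAYER).to_numpy()
    by_pop = {p: np.flatnonzero(neurons["population"].to_numpy() == p)
              for p in pops}

    cols: dict[str, list] = {
        "pre_id": [], "post_id": [], "delay_ms": [], "n_synapses": [],
        "placement": [], "AMPA": [], "NMDA": [], "GABAA_fast": [],
        "GABAA_slow": [], "GABAB": [],
    }
    for pre_pop in pops:
        pre_idx = by_pop[pre_pop]
        pre_cls = _pre_class(pre_pop)
        for post_pop in pops:
            rule = ruleset.get(pre_pop, post_pop)
            p0 = rule.pcon
            if p0 == 0.0:
                continue
            post_idx = by_pop[post_pop]
            d = np.linalg.norm(
                pos[pre_idx][:, None, :] - pos[post_idx][None, :, :],
                axis=2,
            )
            p = p0 * np.exp(-d / rule.decay_um) * corr[post_idx][None, :]
            np.clip(p, 0.0, 1.0, out=p)
            if rule.same_layer_only:
                same = (
                    layer_of[pre_idx][:, None]
                    == layer_of[post_idx][None, :]
                )
                p = p * same
            if pre_pop == post_pop:
                np.fill_diagonal(p, 0.0)
            hit = rng.random(p.shape) < p
            ii, jj = np.nonzero(hit)
            if ii.size == 0:
                continue
            detail = (
                "detailed" if post_pop in DETAILED_POPULATIONS else "reduced"
            )
            post_ei = (
                "inhibitory"
                if post_pop.startswith(("PV", "SOM"))
                else "excitatory"
            )
            n_syn, weights = split_unitary_weight(
                rule.vcon, detail, pre_cls, post_ei
            )
            if pre_cls == "PV" and post_ei == "excitatory":
                placement = "perisomatic"
            elif pre_cls == "SOM" and post_ei == "excitatory":
                placement = "apical"
            elif post_ei == "inhibitory":
                placement = "apical"
            else:
                placement = "uniform"
            delays = conduction_delay(d[ii, jj] / 1000.0)
            cols["pre_id"].extend(ids[pre_idx[ii]])
            cols["post_id"].extend(ids[post_idx[jj]])
            cols["delay_ms"].extend(np.asarray(delays).tolist())
            cols["n_synapses"].extend([n_syn] * ii.size)
            cols["placement"].extend([placement] * ii.size)
            for receptor in ("AMPA", "NMDA", "GABAA_fast", "GABAA_slow",
                             "GABAB"):
                cols[receptor].extend(
                    [weights.get(receptor, 0.0)] * ii.size
                )
    edges = pd.DataFrame(cols)
    return NetworkSpec(geometry=config.geometry, neurons=neurons, edges=edges)


def export_network(spec: NetworkSpec, path) -> None:
    """Write a network as structured text (JSON nodes + edges tables)."""
    doc = {
        "schema_version": 1,
        "geometry": {
            "diameter_um": spec.geometry.diameter_um,
            "depth_um": spec.geometry.depth_um,
            "layer_bands": {
                k: list(v) for k, v in spec.geometry.layer_bands.items()
            },
        },
        "nodes": spec.neurons.reset_index().to_dict(orient="list"),
        "edges": spec.edges.to_dict(orient="list"),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def import_network(path) -> NetworkSpec:
    with open(path) as fh:
        doc = json.load(fh)
    geom = ColumnGeometry(
        diameter_um=doc["geometry"]["diameter_um"],
        depth_um=doc["geometry"]["depth_um"],
        layer_bands={
            k: tuple(v) for k, v in doc["geometry"]["layer_bands"].items()
        },
    )
    neurons = pd.DataFrame(doc["nodes"]).set_index("id")
    edges = pd.DataFrame(doc["edges"])
    return NetworkSpec(geometry=geom, neurons=neurons, edges=edges)
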