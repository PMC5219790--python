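"""Synthetic single-cell gene-by-environment experiments with ground truth.

The generator emulates the chip design of the study this package's analytics
target: replicate microfluidic chips of up to 48 single-macrophage chambers,
each chip cultured for one or eight hours, every chip carrying the eight
populations given by 2 genotypes (WT / SAMHD1-style KO) x 4 media conditions
(standard or conditioned media, with or without LPS).  Latent cell states with
condition-dependent proportions, global-shift genes, subtype-specific
(heterogeneous) genes and genotype-by-environment genes are planted on top of
an overdispersed count model:

* per-gene baseline abundance: log-normal;
* state programs and effects: multiplicative (log2 fold changes), with
  per-cell renormalisation (sequencing is compositional);
* counts: negative binomial (gamma-Poisson) around a log-normal per-cell
  library size; independent Bernoulli dropout zeroing afterwards.

Everything is a pure function of (config, seed): per-module substreams let
the expression matrix and the chamber images be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import ChamberImage
from .qc import ExpressionMatrix

__all__ = [
    "StateSpec",
    "ImagingConfig",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedExperiment",
    "simulate_experiment",
    "simulate_chamber_images",
    "iter_chamber_images",
    "random_chambers",
    "study_config",
]

ENVIRONMENTS = ("standard", "standard+LPS", "conditioned", "conditioned+LPS")


@dataclass
class StateSpec:
    """A latent cell state: baseline proportion, optional condition multipliers
    on that proportion, and a gene program (gene index -> log2 effect)."""

    name: str
    proportion: float
    program: dict = field(default_factory=dict)          # gene index -> log2 FC
    multipliers: dict = field(default_factory=dict)      # env label or "1h"/"8h" -> x


@dataclass
class ImagingConfig:
    shape: tuple = (72, 96)
    bg_mean: float = 200.0
    bg_sd: float = 8.0
    cell_amplitude: float = 3000.0
    amplitude_jitter: float = 0.2
    cell_sigma_px: float = 2.5
    motility_sigma_px: float = 2.0
    bead_center: tuple = (10.0, 10.0)
    bead_radius: float = 3.0
    bead_amplitude: float = 1500.0
    margin_px: int = 16
    min_separation_px: float = 16.0
    pixel_size_um: float = 5.5
    max_timepoints: int = 8


@dataclass
class SimulationConfig:
    n_chips: int = 10
    cells_per_chip: int = 48
    time_per_chip: list | None = None          # hours per chip; default alternates 1/8
    genotype_fraction: float = 0.5             # fraction KO per chip
    n_genes: int = 2000
    states: list = field(default_factory=lambda: [StateSpec("state1", 1.0)])
    global_de: dict = field(default_factory=dict)    # gene -> log2 effect (all states)
    het_de: dict = field(default_factory=dict)       # gene -> {state name -> log2 effect}
    gxe: dict = field(default_factory=dict)          # gene -> (log2 effect, (env labels,))
    contrast: str = "genotype"                 # which factor carries the effects
    rogue_state: StateSpec | None = None       # state present on a single chip only
    rogue_state_chip: int | None = None
    dropout_rate: float = 0.1
    dispersion: float = 4.0                    # NB size parameter theta
    library_size: float = 1e5
    library_size_sigma: float = 0.35
    abundance_sigma: float = 1.5               # sd of log gene abundance
    mean_gene_length: float = 1500.0
    gene_length_sigma: float = 0.45
    n_bulk_controls_per_chip: int = 0
    doublet_rate: float = 0.0
    low_cdna_rate: float = 0.0
    cdna_floor: float = 0.05
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self):
        if not (1 <= self.cells_per_chip <= 48):
            raise ValueError("cells_per_chip must be in 1..48 (chamber count)")
        if self.n_chips < 1 or self.n_genes < 1:
            raise ValueError("n_chips and n_genes must be positive")
        if self.time_per_chip is None:
            self.time_per_chip = [1 if c % 2 == 0 else 8 for c in range(self.n_chips)]
        if len(self.time_per_chip) != self.n_chips:
            raise ValueError("time_per_chip must list one time per chip")
        if any(t not in (1, 8) for t in self.time_per_chip):
            raise ValueError("chip times must be 1 or 8 hours")
        props = [s.proportion for s in self.states]
        if abs(sum(props) - 1.0) > 1e-6:
            raise ValueError("state proportions must sum to 1")
        if self.contrast not in ("genotype", "time"):
            raise ValueError("contrast must be 'genotype' or 'time'")
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise ValueError("state names must be unique")
        if (self.rogue_state is None) != (self.rogue_state_chip is None):
            raise ValueError("rogue_state and rogue_state_chip must be set together")
        if self.rogue_state_chip is not None and not (0 <= self.rogue_state_chip < self.n_chips):
            raise ValueError("rogue_state_chip out of range")
        all_effect_genes = []
        for g in self.global_de:
            all_effect_genes.append(g)
        for g in self.het_de:
            all_effect_genes.append(g)
            bad = set(self.het_de[g]) - set(names)
            if bad:
                raise ValueError(f"het_de gene {g} references unknown states {bad}")
        for g, (_, envs) in self.gxe.items():
            all_effect_genes.append(g)
            bad = set(envs) - set(ENVIRONMENTS)
            if bad:
                raise ValueError(f"gxe gene {g} references unknown environments {bad}")
        if any(not (0 <= g < self.n_genes) for g in all_effect_genes):
            raise ValueError("effect on nonexistent gene index")
        if len(set(all_effect_genes)) != len(all_effect_genes):
            raise ValueError("global/het/gxe gene sets must be mutually exclusive")
        for s in list(self.states) + ([self.rogue_state] if self.rogue_state else []):
            if any(not (0 <= g < self.n_genes) for g in s.program):
                raise ValueError(f"state {s.name} program addresses nonexistent gene")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass
class GroundTruth:
    true_state: pd.Series                      # per cell
    true_global_de: dict                       # gene id -> log2 effect
    true_het_de: dict                          # gene id -> {state -> log2 effect}
    true_gxe: dict                             # gene id -> (log2 effect, envs)
    state_programs: dict                       # state name -> {gene id -> log2 effect}
    true_image_cells: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "true_state": self.true_state.to_dict(),
            "true_global_de": {str(k): v for k, v in self.true_global_de.items()},
            "true_het_de": {str(k): v for k, v in self.true_het_de.items()},
            "true_gxe": {str(k): [v[0], list(v[1])] for k, v in self.true_gxe.items()},
            "state_programs": {s: {str(g): e for g, e in prog.items()}
                               for s, prog in self.state_programs.items()},
            "true_image_cells": self.true_image_cells,
        }


@dataclass
class SimulatedExperiment:
    expression: ExpressionMatrix               # counts
    gene_lengths: pd.Series
    metadata: pd.DataFrame                     # indexed by cell id
    truth: GroundTruth
    config: SimulationConfig


def _gene_id(i: int) -> str:
    return f"G{i:05d}"


def _allocate_chambers(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic chamber allocation mirroring the 8-populations-per-chip
    layout: environments cycle over chambers, genotypes balanced within each
    environment."""
    rows = []
    for chip in range(config.n_chips):
        n = config.cells_per_chip
        env_members: dict[str, list[int]] = {e: [] for e in ENVIRONMENTS}
        for chamber in range(n):
            env_members[ENVIRONMENTS[chamber % 4]].append(chamber)
        scheme = "double=KO" if chip % 2 == 0 else "double=WT"
        for env, members in env_members.items():
            n_ko = int(round(config.genotype_fraction * len(members)))
            for j, chamber in enumerate(members):
                rows.append(
                    {
                        "cell_id": f"chip{chip}_c{chamber:02d}",
                        "chip": chip,
                        "chamber": chamber,
                        "genotype": "KO" if j < n_ko else "WT",
                        "env": env,
                        "media": env.split("+")[0],
                        "lps": env.endswith("+LPS"),
                        "time_h": config.time_per_chip[chip],
                        "stain_scheme": scheme,
                        "library_id": f"chip{chip}",
                    }
                )
    return pd.DataFrame(rows).set_index("cell_id").sort_values(["chip", "chamber"])


def _state_probs(config: SimulationConfig, env: str, time_h: int, on_rogue_chip: bool):
    states = list(config.states)
    props = np.array([s.proportion for s in states], dtype=float)
    for i, s in enumerate(states):
        for key, mult in s.multipliers.items():
            if key == env or key == f"{time_h}h":
                props[i] *= mult
    if on_rogue_chip and config.rogue_state is not None:
        p_rogue = config.rogue_state.proportion
        props = props / props.sum() * (1 - p_rogue)
        states = states + [config.rogue_state]
        props = np.append(props, p_rogue)
    else:
        props = props / props.sum()
    return [s.name for s in states], props


def _program_lookup(config: SimulationConfig) -> dict:
    progs = {s.name: dict(s.program) for s in config.states}
    if config.rogue_state is not None:
        progs[config.rogue_state.name] = dict(config.rogue_state.program)
    return progs


def _effect_vector(config: SimulationConfig, state: str, genotype: str, env: str,
                   time_h: int, programs: dict) -> np.ndarray:
    """log2 multiplicative effects for one cell profile."""
    eff = np.zeros(config.n_genes)
    for g, lfc in programs[state].items():
        eff[g] += lfc
    at_level2 = (genotype == "KO") if config.contrast == "genotype" else (time_h == 8)
    if at_level2:
        for g, lfc in config.global_de.items():
            eff[g] += lfc
        for g, per_state in config.het_de.items():
            eff[g] += per_state.get(state, 0.0)
    if genotype == "KO":  # genotype-by-environment effects are KO effects
        for g, (lfc, envs) in config.gxe.items():
            if env in envs:
                eff[g] += lfc
    return eff


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate counts, metadata and ground truth for the configured design."""
    config.validate()
    rng = np.random.default_rng([config.seed, 11])

    gene_ids = [_gene_id(i) for i in range(config.n_genes)]
    abundance = np.exp(rng.normal(0.0, config.abundance_sigma, config.n_genes))
    lengths = np.maximum(
        np.exp(rng.normal(math.log(config.mean_gene_length), config.gene_length_sigma,
                          config.n_genes)),
        200.0,
    ).round()
    gene_lengths = pd.Series(lengths, index=gene_ids, name="length")

    meta = _allocate_chambers(config)
    programs = _program_lookup(config)

    # latent state per cell
    state_col = []
    for cell_id, row in meta.iterrows():
        names, probs = _state_probs(config, row["env"], row["time_h"],
                                    row["chip"] == config.rogue_state_chip)
        state_col.append(names[rng.choice(len(names), p=probs)])
    meta = meta.assign(true_state=state_col)

    # expected relative expression per distinct cell profile
    profile_keys = {}
    profile_p = []
    profile_idx = np.empty(len(meta), dtype=int)
    for i, (_, row) in enumerate(meta.iterrows()):
        key = (row["true_state"], row["genotype"], row["env"], row["time_h"])
        if key not in profile_keys:
            eff = _effect_vector(config, *key, programs)
            e = abundance * np.exp2(eff)
            profile_keys[key] = len(profile_p)
            profile_p.append(e / e.sum())
        profile_idx[i] = profile_keys[key]
    P = np.column_stack(profile_p)                      # genes x profiles

    lib = np.exp(rng.normal(math.log(config.library_size), config.library_size_sigma,
                            len(meta)))
    mu = P[:, profile_idx] * lib[None, :]
    counts = rng.poisson(rng.gamma(config.dispersion, mu / config.dispersion)).astype(float)

    # doublets: add a second cell's worth of counts
    doublet = np.zeros(len(meta), dtype=bool)
    if config.doublet_rate > 0:
        doublet = rng.random(len(meta)) < config.doublet_rate
        for ci in np.flatnonzero(doublet):
            extra_mu = P[:, profile_idx[ci]] * lib[ci]
            counts[:, ci] += rng.poisson(
                rng.gamma(config.dispersion, extra_mu / config.dispersion))

    if config.dropout_rate > 0:
        counts[rng.random(counts.shape) < config.dropout_rate] = 0.0

    cdna = np.exp(rng.normal(0.0, 0.3, len(meta)))
    if config.low_cdna_rate > 0:
        low = rng.random(len(meta)) < config.low_cdna_rate
        cdna[low] = config.cdna_floor * 0.2
    meta = meta.assign(
        doublet=doublet,
        bead_contact=False,
        cdna_ng_ul=cdna,
        is_bulk=False,
    )

    cell_ids = list(meta.index)
    values = counts
    # bulk controls: deeper, tighter libraries of the state-mixture profile
    if config.n_bulk_controls_per_chip > 0:
        bulk_cols = []
        bulk_rows = []
        base_mix = np.zeros(config.n_genes)
        for s in config.states:
            e = abundance * np.exp2(_effect_vector(config, s.name, "WT",
                                                   "standard", 1, programs))
            base_mix += s.proportion * e / e.sum()
        base_mix /= base_mix.sum()
        for chip in range(config.n_chips):
            for b in range(config.n_bulk_controls_per_chip):
                bid = f"chip{chip}_bulk{b}"
                mu_b = base_mix * config.library_size * 10
                bulk_cols.append(rng.poisson(rng.gamma(50.0, mu_b / 50.0)).astype(float))
                bulk_rows.append(
                    {
                        "cell_id": bid, "chip": chip, "chamber": -1,
                        "genotype": "bulk", "env": "standard", "media": "standard",
                        "lps": False, "time_h": config.time_per_chip[chip],
                        "stain_scheme": "none", "library_id": f"chip{chip}",
                        "true_state": "bulk", "doublet": False, "bead_contact": False,
                        "cdna_ng_ul": 5.0, "is_bulk": True,
                    }
                )
        values = np.column_stack([values] + bulk_cols)
        cell_ids = cell_ids + [r["cell_id"] for r in bulk_rows]
        meta = pd.concat([meta, pd.DataFrame(bulk_rows).set_index("cell_id")])

    expr = ExpressionMatrix(values, gene_ids, cell_ids, unit="counts")
    truth = GroundTruth(
        true_state=meta["true_state"].copy(),
        true_global_de={_gene_id(g): v for g, v in config.global_de.items()},
        true_het_de={_gene_id(g): dict(v) for g, v in config.het_de.items()},
        true_gxe={_gene_id(g): (v[0], tuple(v[1])) for g, v in config.gxe.items()},
        state_programs={s: {_gene_id(g): e for g, e in prog.items()}
                        for s, prog in programs.items()},
    )
    return SimulatedExperiment(expr, gene_lengths, meta, truth, config)


# ---------------------------------------------------------------------------
# chamber images
# ---------------------------------------------------------------------------

def _render_chamber(rng, img: ImagingConfig, cells, bead: bool) -> np.ndarray:
    h, w = img.shape
    grid = rng.normal(img.bg_mean, img.bg_sd, (h, w))
    rr, cc = np.mgrid[0:h, 0:w]
    for (cy, cx), amp in cells:
        grid += amp * np.exp(-((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * img.cell_sigma_px ** 2))
    if bead:
        by, bx = img.bead_center
        grid += img.bead_amplitude * ((rr - by) ** 2 + (cc - bx) ** 2 <= img.bead_radius ** 2)
    return np.clip(grid, 0, 65535)


def _place_centers(rng, img: ImagingConfig, n: int) -> list:
    centers = []
    h, w = img.shape
    for _ in range(n):
        for _attempt in range(200):
            c = (rng.uniform(img.margin_px, h - img.margin_px),
                 rng.uniform(img.margin_px, w - img.margin_px))
            if all(math.dist(c, o) >= img.min_separation_px for o in centers):
                centers.append(c)
                break
        else:
            raise ValueError("cannot place cells with the configured separation")
    return centers


def iter_chamber_images(config: SimulationConfig):
    """Yield (chamber_id, {channel: {timepoint: ChamberImage}}, truth_cells).

    One occupied chamber per cell of the expression design; motility is a
    Gaussian random walk per hourly timepoint; double-stained cells appear in
    both fluorescent channels, single-stained in orange only; a retention
    bead is rendered at a fixed position in the brightfield channel.
    """
    config.validate()
    img = config.imaging
    meta = _allocate_chambers(config)
    rng = np.random.default_rng([config.seed, 23])
    for cell_id, row in meta.iterrows():
        chamber_id = cell_id
        timepoints = list(range(0, min(int(row["time_h"]), img.max_timepoints) + 1))
        centers0 = _place_centers(rng, img, 1)
        amp = img.cell_amplitude * rng.uniform(1 - img.amplitude_jitter,
                                               1 + img.amplitude_jitter)
        double = (row["stain_scheme"] == f"double={row['genotype']}")
        stained = ["orange", "green"] if double else ["orange"]
        track = {0: centers0[0]}
        for t in timepoints[1:]:
            prev = track[max(k for k in track if k < t)]
            step = rng.normal(0, img.motility_sigma_px, 2)
            track[t] = (
                float(np.clip(prev[0] + step[0], img.margin_px, img.shape[0] - img.margin_px)),
                float(np.clip(prev[1] + step[1], img.margin_px, img.shape[1] - img.margin_px)),
            )
        channels: dict = {}
        for channel in ("brightfield", "orange", "green"):
            channels[channel] = {}
            for t in timepoints:
                cells = []
                if channel in stained:
                    cells = [(track[t], amp)]
                elif channel == "brightfield":
                    cells = [(track[t], amp * 0.15)]
                grid = _render_chamber(rng, img, cells, bead=(channel == "brightfield"))
                channels[channel][t] = ChamberImage(
                    pixels=grid, channel=channel, timepoint_hours=t,
                    chamber_id=chamber_id, pixel_size_um=img.pixel_size_um,
                )
        truth_cells = [
            {
                "centers": {str(t): list(track[t]) for t in timepoints},
                "stained": stained,
                "genotype": row["genotype"],
            }
        ]
        yield chamber_id, channels, truth_cells


def simulate_chamber_images(config: SimulationConfig):
    """Materialise all chamber images; returns (images, true_image_cells)."""
    images = []
    truth: dict = {}
    for chamber_id, channels, cells in iter_chamber_images(config):
        for channel, by_t in channels.items():
            images.extend(by_t.values())
        truth[chamber_id] = cells
    return images, truth


def random_chambers(n_chambers: int, seed: int, cells_range: tuple = (0, 3),
                    imaging: ImagingConfig | None = None):
    """Standalone random single-channel chambers with known cell centers.

    Returns a list of (ChamberImage, [centers]); used to measure detection
    recall/precision against ground truth.
    """
    img = imaging or ImagingConfig()
    rng = np.random.default_rng([seed, 37])
    out = []
    for i in range(n_chambers):
        n_cells = int(rng.integers(cells_range[0], cells_range[1] + 1))
        centers = _place_centers(rng, img, n_cells)
        cells = [
            (c, img.cell_amplitude * rng.uniform(1 - img.amplitude_jitter,
                                                 1 + img.amplitude_jitter))
            for c in centers
        ]
        grid = _render_chamber(rng, img, cells, bead=False)
        out.append(
            (ChamberImage(pixels=grid, channel="orange", timepoint_hours=0,
                          chamber_id=f"rand{i:03d}", pixel_size_um=img.pixel_size_um),
             centers)
        )
    return out


# ---------------------------------------------------------------------------
# the canonical study-scale configuration
# ---------------------------------------------------------------------------

def study_config(
    seed: int = 0,
    n_chips: int = 10,
    cells_per_chip: int = 48,
    n_genes: int = 2000,
    with_states: bool = True,
    with_effects: bool = False,
    rogue: bool = False,
    single_time: bool = False,
    **overrides,
) -> SimulationConfig:
    """The frozen study-scale conditions used throughout tests and reports.

    Three latent states at proportions (0.5, 0.3, 0.2) with disjoint 100-gene
    programs at |log2 FC| = 2 (sign alternating within each program); one
    state's proportion responds to LPS in standard media.  With effects: 20
    global-shift genes at +1.5 log2 (KO vs WT across all states) and 20
    heterogeneous genes whose KO effect alternates +-1.5 across the three
    states (overall sign flipped per gene), so every state carries a shift of
    magnitude 1.5 while the cross-state mean shift is small (|mu| = 0.5)
    relative to the heterogeneity (MAD = 4/3).  The optional rogue state
    lives on chip 0 only.
    """
    # program/effect placement scales with the gene count; at the study scale
    # (>= 1000 genes) programs span 100 genes and 20 genes carry each effect
    psize = 100 if n_genes >= 1000 else max(4, n_genes // 10)
    n_eff = 20 if n_genes >= 1000 else max(2, n_genes // 20)
    gstart = n_genes // 20
    hstart = max(n_genes // 10, gstart + n_eff)

    def program(start):
        return {start + j: 2.0 if j % 2 == 0 else -2.0 for j in range(psize)}

    states: list[StateSpec]
    if with_states:
        states = [
            StateSpec("state1", 0.5),
            StateSpec("state2", 0.3, program=program(n_genes - 3 * psize)),
            StateSpec("state3", 0.2, program=program(n_genes - 2 * psize),
                      multipliers={"standard+LPS": 0.4}),
        ]
    else:
        states = [StateSpec("state1", 1.0)]
    global_de = {}
    het_de = {}
    if with_effects:
        global_de = {gstart + i: 1.5 for i in range(n_eff)}
        het_de = {
            hstart + i: {
                "state1": 1.5 * (1 if i % 2 == 0 else -1),
                "state2": -1.5 * (1 if i % 2 == 0 else -1),
                "state3": 1.5 * (1 if i % 2 == 0 else -1),
            }
            for i in range(n_eff)
        }
    rogue_state = None
    rogue_chip = None
    if rogue:
        rogue_state = StateSpec(
            "rogue", 0.25,
            program=program(n_genes - psize),
        )
        rogue_chip = 0
    return SimulationConfig(
        n_chips=n_chips,
        cells_per_chip=cells_per_chip,
        n_genes=n_genes,
        time_per_chip=[8] * n_chips if single_time else None,
        states=states,
        global_de=global_de,
        het_de=het_de,
        rogue_state=rogue_state,
        rogue_state_chip=rogue_chip,
        seed=seed,
        **overrides,
    )
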