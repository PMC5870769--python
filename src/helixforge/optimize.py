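"""Bounded differential-evolution fitting of specifications to structures.

The optimizer is DE/rand/1/bin: a parent population sampled uniformly in
the search box; per generation each member receives a mutant
``a + F·(b − c)`` built from three distinct other members, binomial
crossover at rate CR with one forced dimension, clipping to bounds and
greedy selection.  The default fitness for structure fitting is the
superposed backbone RMSD between the built model and the target.

Total model evaluations are ``population × (generations + 1)``: the
parent generation plus one candidate population per generation.

The fitting surface follows the model/results idiom: build a
:class:`StructureFit` from a target assembly, call :meth:`~StructureFit.fit`,
and read estimates and diagnostics off the returned :class:`FitResult`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .core import Assembly
from .geometry import (backbone_coordinates, backbone_rmsd, rmsd100,
                       superpose, RMSD100_MIN_RESIDUES)
from .specifications import (ALPHA, PPII, CrickParams, HelixPairParams,
                             SolenoidParams, build_coiled_coil,
                             build_helix_pair, build_solenoid,
                             build_tropocollagen)
from .specifications.assemblies import (canonicalize_unit, coiled_coil_coords,
                                        helix_pair_coords, solenoid_coords)

__all__ = [
    "ParameterSpec", "OptimizerConfig", "FitResult", "StructureFit",
    "total_evaluations", "run_de", "fit_structure",
    "two_stage_solenoid_fit", "default_ranges", "DEFAULT_RANGES",
]


@dataclass(frozen=True)
class ParameterSpec:
    """One bounded search dimension: a specification field name, its
    lower/upper bounds and whether it is continuous or integer-valued."""

    name: str
    lower: float
    upper: float
    kind: str = "continuous"

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(
                f"{self.name}: lower bound {self.lower} must be below "
                f"upper bound {self.upper}")
        if self.kind not in ("continuous", "integer"):
            raise ValueError(f"{self.name}: kind must be 'continuous' or "
                             f"'integer', got {self.kind!r}")


@dataclass(frozen=True)
class OptimizerConfig:
    """Differential-evolution settings.

    ``F`` is the differential weight, ``CR`` the crossover rate; the
    defaults are standard DE values.  A single ``seed`` governs all
    stochastic draws, making runs bit-reproducible.
    """

    population: int = 20
    generations: int = 50
    seed: int = 0
    F: float = 0.75
    CR: float = 0.8

    def __post_init__(self):
        if self.population < 4:
            raise ValueError("population must be >= 4 for DE/rand/1")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not (0.0 < self.F < 2.0):
            raise ValueError("F must be in (0, 2)")
        if not (0.0 <= self.CR <= 1.0):
            raise ValueError("CR must be in [0, 1]")


@dataclass
class FitResult:
    """Result of a differential-evolution fit.

    ``history`` holds the best score seen up to and including each
    generation (index 0 = parent generation), and is non-increasing.
    """

    best_params: dict
    best_score: float
    history: list[float]
    n_evaluations: int
    best_model: Assembly | None = None
    spec_name: str | None = None
    stage1: "FitResult | None" = None
    n_residues: int | None = None

    @property
    def best_rmsd(self) -> float:
        return self.best_score

    @property
    def best_rmsd100(self) -> float | None:
        if self.n_residues is None or self.n_residues < RMSD100_MIN_RESIDUES:
            return None
        return rmsd100(self.best_score, self.n_residues)

    def summary(self) -> str:
        lines = ["Differential-evolution fit"]
        lines.append("=" * 46)
        if self.spec_name:
            lines.append(f"{'Specification:':<26}{self.spec_name}")
        lines.append(f"{'Best score (RMSD, Å):':<26}{self.best_score:.4f}")
        if self.best_rmsd100 is not None:
            lines.append(f"{'RMSD100 (Å):':<26}{self.best_rmsd100:.4f}")
        if self.n_residues is not None:
            lines.append(f"{'Residues:':<26}{self.n_residues}")
        lines.append(f"{'Model evaluations:':<26}{self.n_evaluations}")
        lines.append(f"{'Generations:':<26}{len(self.history) - 1}")
        lines.append("-" * 46)
        lines.append("Best parameters:")
        for name, value in self.best_params.items():
            if isinstance(value, float):
                lines.append(f"  {name:<24}{value:12.4f}")
            else:
                lines.append(f"  {name:<24}{value!r:>12}")
        if self.stage1 is not None:
            lines.append("-" * 46)
            lines.append("Stage 1 (repeat unit) best score: "
                         f"{self.stage1.best_score:.4f} Å")
        return "\n".join(lines)


def total_evaluations(population: int, generations: int) -> int:
    """Total model evaluations: one parent generation plus one candidate
    population per generation."""
    if population < 1 or generations < 0:
        raise ValueError("population must be >= 1 and generations >= 0")
    return population * (generations + 1)


def _round_integers(vec: np.ndarray, specs: Sequence[ParameterSpec]) -> dict:
    out = {}
    for value, spec in zip(vec, specs):
        out[spec.name] = int(round(value)) if spec.kind == "integer" else float(value)
    return out


def run_de(objective: Callable[[dict], float],
           specs: Sequence[ParameterSpec],
           cfg: OptimizerConfig) -> FitResult:
    """Minimize ``objective`` over the box with DE/rand/1/bin.

    ``objective`` receives a name→value dict (integer dimensions already
    rounded).  Deterministic for a given config.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("at least one ParameterSpec is required")
    rng = np.random.default_rng(cfg.seed)
    lower = np.array([s.lower for s in specs])
    upper = np.array([s.upper for s in specs])
    dim = len(specs)
    npop = cfg.population

    pop = lower + rng.random((npop, dim)) * (upper - lower)
    scores = np.array([objective(_round_integers(x, specs)) for x in pop])
    n_evals = npop
    n_bad = int(np.sum(~np.isfinite(scores)))
    if n_bad > npop / 2:
        raise ValueError(
            f"objective returned non-finite values for {n_bad}/{npop} "
            f"parent members; review the parameter ranges")
    scores = np.where(np.isfinite(scores), scores, np.inf)

    best_idx = int(np.argmin(scores))
    history = [float(scores[best_idx])]

    for _ in range(cfg.generations):
        for i in range(npop):
            choices = [j for j in range(npop) if j != i]
            a, b, c = rng.choice(choices, size=3, replace=False)
            mutant = pop[a] + cfg.F * (pop[b] - pop[c])
            cross = rng.random(dim) < cfg.CR
            cross[rng.integers(dim)] = True      # one forced dimension
            trial = np.where(cross, mutant, pop[i])
            trial = np.clip(trial, lower, upper)
            score = objective(_round_integers(trial, specs))
            n_evals += 1
            if not math.isfinite(score):
                score = math.inf
            if score <= scores[i]:
                pop[i] = trial
                scores[i] = score
        history.append(float(scores.min()))

    best_idx = int(np.argmin(scores))
    return FitResult(
        best_params=_round_integers(pop[best_idx], specs),
        best_score=float(scores[best_idx]),
        history=history,
        n_evaluations=n_evals,
    )


# ---------------------------------------------------------------------------
# Specification registry: flat parameter dicts -> built assemblies.

def _build_coiled_coil_flat(params: dict) -> Assembly:
    return build_coiled_coil(_crick_from_flat(params), params.get("cls", ALPHA))


def _crick_from_flat(params: dict) -> CrickParams:
    n = int(params["n_chains"])
    def per_chain(stem, default):
        keys = [f"{stem}_{k}" for k in range(1, n + 1)]
        if any(k in params for k in keys):
            return [float(params.get(k, default)) for k in keys]
        return params.get(stem, default)
    return CrickParams(
        n_chains=n,
        superhelix_radius=float(params["superhelix_radius"]),
        pitch=float(params["pitch"]),
        interface_angle=float(params.get("interface_angle", 0.0)),
        n_residues=params["n_residues"],
        z_shift=per_chain("z_shift", 0.0),
        chain_rotation=per_chain("chain_rotation", 0.0),
        orientation=params.get("orientation", "parallel"),
        superhelix_handedness=params.get("superhelix_handedness", "left"),
    )


def _build_tropocollagen_flat(params: dict) -> Assembly:
    params = dict(params)
    params.setdefault("superhelix_handedness", "right")
    params.setdefault("n_chains", 3)
    return build_tropocollagen(_crick_from_flat(params), params.get("cls", PPII))


def _helix_pair_from_flat(params: dict) -> HelixPairParams:
    def pair(stem, default):
        keys = (f"{stem}_1", f"{stem}_2")
        if any(k in params for k in keys):
            return tuple(float(params.get(k, default)) for k in keys)
        return params.get(stem, (default, default))
    return HelixPairParams(
        axis_distance=pair("axis_distance", 3.0),
        z_shift=pair("z_shift", 0.0),
        phi_ca=pair("phi_ca", 0.0),
        splay=pair("splay", 0.0),
        off_plane_rotation=pair("off_plane_rotation", 0.0),
        helix_lengths=tuple(params["helix_lengths"]),
    )


def _build_helix_pair_flat(params: dict) -> Assembly:
    return build_helix_pair(_helix_pair_from_flat(params),
                            params.get("cls", ALPHA))


def _build_solenoid_flat(params: dict) -> Assembly:
    return build_solenoid(SolenoidParams(
        repeat_unit=params["repeat_unit"],
        n_repeats=int(params["n_repeats"]),
        radius=float(params["radius"]),
        rise_per_repeat=float(params["rise_per_repeat"]),
        twist_per_repeat=float(params["twist_per_repeat"]),
        handedness=params.get("handedness", "right"),
        unit_rotation=float(params.get("unit_rotation", 0.0)),
    ), params.get("cls", ALPHA))


SPEC_BUILDERS: dict[str, Callable[[dict], Assembly]] = {
    "coiled_coil": _build_coiled_coil_flat,
    "tropocollagen": _build_tropocollagen_flat,
    "helix_pair": _build_helix_pair_flat,
    "solenoid": _build_solenoid_flat,
}


# Packaged default search ranges.  Coiled-coil radius bounds are keyed by
# oligomer state; pitch and interface-angle bounds are shared.  The
# collagen and ankyrin-style sets mirror the corresponding rebuild
# protocols (z-shifts and rotations per chain; two-stage solenoid).
DEFAULT_RANGES: dict[str, list[ParameterSpec]] = {
    "coiled_coil_dimer": [
        ParameterSpec("superhelix_radius", 3.5, 5.5),
        ParameterSpec("pitch", 50.0, 350.0),
        ParameterSpec("interface_angle", -20.0, 20.0),
    ],
    "coiled_coil_trimer": [
        ParameterSpec("superhelix_radius", 5.0, 7.0),
        ParameterSpec("pitch", 50.0, 350.0),
        ParameterSpec("interface_angle", -20.0, 20.0),
    ],
    "coiled_coil_tetramer": [
        ParameterSpec("superhelix_radius", 5.5, 8.5),
        ParameterSpec("pitch", 50.0, 350.0),
        ParameterSpec("interface_angle", -20.0, 20.0),
    ],
    "coiled_coil_pentamer": [
        ParameterSpec("superhelix_radius", 6.5, 9.5),
        ParameterSpec("pitch", 50.0, 350.0),
        ParameterSpec("interface_angle", -20.0, 20.0),
    ],
    "tropocollagen": [
        ParameterSpec("superhelix_radius", 1.5, 5.5),
        ParameterSpec("pitch", 25.0, 105.0),
        ParameterSpec("interface_angle", -180.0, 180.0),
        ParameterSpec("z_shift_1", 0.0, 6.2),
        ParameterSpec("z_shift_2", 0.0, 6.2),
        ParameterSpec("z_shift_3", 0.0, 6.2),
        ParameterSpec("chain_rotation_1", -30.0, 30.0),
        ParameterSpec("chain_rotation_2", -30.0, 30.0),
        ParameterSpec("chain_rotation_3", -30.0, 30.0),
    ],
    "helix_pair": [
        ParameterSpec("axis_distance_1", 0.0, 6.0),
        ParameterSpec("axis_distance_2", 0.0, 6.0),
        ParameterSpec("z_shift_1", -6.0, 6.0),
        ParameterSpec("z_shift_2", -6.0, 6.0),
        ParameterSpec("phi_ca_1", -180.0, 180.0),
        ParameterSpec("phi_ca_2", -180.0, 180.0),
        ParameterSpec("splay_1", -45.0, 5.0),
        ParameterSpec("splay_2", -45.0, 5.0),
        ParameterSpec("off_plane_rotation_1", 90.0, 270.0),
        ParameterSpec("off_plane_rotation_2", 90.0, 270.0),
    ],
    "solenoid": [
        ParameterSpec("radius", 25.0, 45.0),
        ParameterSpec("rise_per_repeat", 2.0, 18.0),
        ParameterSpec("twist_per_repeat", -180.0, 180.0),
        ParameterSpec("unit_rotation", 0.0, 360.0),
    ],
}


def default_ranges(spec_name: str, oligomer_state: int | None = None
                   ) -> list[ParameterSpec]:
    """Packaged default search ranges for a specification.

    For ``coiled_coil`` an oligomer state of 2–5 selects the
    corresponding radius range.
    """
    if spec_name == "coiled_coil":
        states = {2: "dimer", 3: "trimer", 4: "tetramer", 5: "pentamer"}
        if oligomer_state not in states:
            raise ValueError(
                f"no packaged coiled-coil ranges for oligomer state "
                f"{oligomer_state}; available: {sorted(states)}")
        return list(DEFAULT_RANGES[f"coiled_coil_{states[oligomer_state]}"])
    if spec_name not in DEFAULT_RANGES:
        raise ValueError(f"no packaged ranges for {spec_name!r}; "
                         f"available: {sorted(DEFAULT_RANGES)}")
    return list(DEFAULT_RANGES[spec_name])


def _preprocess_target(target: Assembly) -> Assembly:
    """Convert hydroxyproline to proline (backbone-identical)."""
    target = target.copy()
    for res in target.residues():
        if res.mol_code == "HYP":
            res.mol_code = "PRO"
    return target


class StructureFit:
    """Parametric fit of a specification to a target structure.

    Parameters
    ----------
    target : Assembly
        Backbone-complete structure to reproduce.
    spec_name : str
        One of ``coiled_coil``, ``tropocollagen``, ``helix_pair``,
        ``solenoid``.
    fixed : dict, optional
        Parameters held fixed during the fit (e.g. ``n_chains``).  Chain
        and residue counts are taken from the target automatically where
        the specification needs them.
    ranges : list of ParameterSpec, optional
        Search dimensions; defaults to the packaged ranges for the
        specification (for coiled coils, selected by the target's chain
        count).

    The fitness is the superposed backbone RMSD between the built model
    and the target.
    """

    def __init__(self, target: Assembly, spec_name: str,
                 fixed: dict | None = None,
                 ranges: Sequence[ParameterSpec] | None = None):
        if spec_name not in SPEC_BUILDERS:
            raise ValueError(f"unknown specification {spec_name!r}; "
                             f"available: {sorted(SPEC_BUILDERS)}")
        self.spec_name = spec_name
        self.target = _preprocess_target(target)
        self.fixed = dict(fixed or {})
        protein_chains = [c for c in self.target if c.polymer_type == "protein"]
        self._chain_lengths = [len(c) for c in protein_chains]

        if spec_name in ("coiled_coil", "tropocollagen"):
            self.fixed.setdefault("n_chains", len(protein_chains))
            self.fixed.setdefault("n_residues", self._chain_lengths)
        elif spec_name == "helix_pair":
            if len(protein_chains) != 2:
                raise ValueError(
                    f"helix_pair target must have 2 chains, got "
                    f"{len(protein_chains)}")
            self.fixed.setdefault("helix_lengths", tuple(self._chain_lengths))

        if ranges is None:
            if spec_name == "coiled_coil":
                ranges = default_ranges("coiled_coil", len(protein_chains))
            else:
                ranges = default_ranges(spec_name)
        self.ranges = list(ranges)

        # Validate the search box and the chain/residue correspondence
        # before any optimization starts.
        midpoint = {s.name: (s.lower + s.upper) / 2.0 for s in self.ranges}
        model = self.build(midpoint)
        model_counts = [len(c) for c in model if c.polymer_type == "protein"]
        if model_counts != self._chain_lengths:
            raise ValueError(
                f"specification output does not match target: per-chain "
                f"residue counts {model_counts} vs {self._chain_lengths}")
        self.n_residues = sum(self._chain_lengths)
        self._target_bb = backbone_coordinates(self.target)
        self._coords_fn = self._make_coords_fn()

    def build(self, params: dict) -> Assembly:
        return SPEC_BUILDERS[self.spec_name]({**self.fixed, **params})

    def _make_coords_fn(self):
        """Array-level model coordinates, bypassing object construction.

        Produces backbone coordinates in the same order as
        :func:`backbone_coordinates` applied to the built assembly.
        """
        if self.spec_name in ("coiled_coil", "tropocollagen"):
            def fn(params):
                merged = {**self.fixed, **params}
                if self.spec_name == "tropocollagen":
                    merged.setdefault("superhelix_handedness", "right")
                p = _crick_from_flat(merged)
                cls = merged.get(
                    "cls", PPII if self.spec_name == "tropocollagen" else ALPHA)
                return np.concatenate(
                    [c.reshape(-1, 3) for c in coiled_coil_coords(p, cls)])
            return fn
        if self.spec_name == "helix_pair":
            def fn(params):
                merged = {**self.fixed, **params}
                p = _helix_pair_from_flat(merged)
                return np.concatenate(
                    [c.reshape(-1, 3)
                     for c in helix_pair_coords(p, merged.get("cls", ALPHA))])
            return fn
        # solenoid: the repeat unit is fixed during a fit, so canonicalize
        # it once up front.
        unit = self.fixed["repeat_unit"]
        if isinstance(unit, HelixPairParams):
            unit = build_helix_pair(unit)
        unit_bb = backbone_coordinates(canonicalize_unit(unit))

        def fn(params):
            merged = {**self.fixed, **params}
            p = SolenoidParams(
                repeat_unit=None,
                n_repeats=int(merged["n_repeats"]),
                radius=float(merged["radius"]),
                rise_per_repeat=float(merged["rise_per_repeat"]),
                twist_per_repeat=float(merged["twist_per_repeat"]),
                handedness=merged.get("handedness", "right"),
                unit_rotation=float(merged.get("unit_rotation", 0.0)))
            return solenoid_coords(unit_bb, p)
        return fn

    def objective(self, params: dict) -> float:
        """Superposed backbone RMSD of the built model against the target."""
        return superpose(self._coords_fn(params), self._target_bb).rmsd

    def fit(self, cfg: OptimizerConfig | None = None, **kwargs) -> FitResult:
        """Run the differential-evolution fit and return the results."""
        if cfg is None:
            cfg = OptimizerConfig(**kwargs)
        result = run_de(self.objective, self.ranges, cfg)
        result.spec_name = self.spec_name
        result.best_model = self.build(result.best_params)
        result.n_residues = self.n_residues
        return result


def fit_structure(target: Assembly, spec_name: str,
                  fixed: dict | None = None,
                  ranges: Sequence[ParameterSpec] | None = None,
                  cfg: OptimizerConfig | None = None) -> FitResult:
    """Functional wrapper: fit a specification's parameters to a target."""
    return StructureFit(target, spec_name, fixed=fixed, ranges=ranges).fit(
        cfg or OptimizerConfig())


def _slice_repeat(target: Assembly, chains_per_repeat: int,
                  index: int) -> Assembly:
    """Deep-copy one repeat (a block of consecutive chains) of a target."""
    tmp = target.copy()
    out = Assembly(id=f"repeat_{index}")
    for chain in list(tmp)[index * chains_per_repeat:
                           (index + 1) * chains_per_repeat]:
        chain.parent = None
        out.add_polymer(chain)
    return out


def two_stage_solenoid_fit(target: Assembly,
                           unit_ranges: Sequence[ParameterSpec] | None = None,
                           solenoid_ranges: Sequence[ParameterSpec] | None = None,
                           cfg1: OptimizerConfig | None = None,
                           cfg2: OptimizerConfig | None = None,
                           chains_per_repeat: int = 2) -> FitResult:
    """Two-stage solenoid fit.

    Stage 1 fits a two-helix repeat unit to the first repeat of the
    target; stage 2 fixes the optimized unit and fits the helical
    symmetry (radius, rise, twist, unit rotation) to the full target.
    Per-stage seeds are derived deterministically from ``cfg1.seed``
    (stage 2 uses ``seed + 1`` unless ``cfg2`` sets its own).
    """
    n_chains = len(list(target))
    if n_chains % chains_per_repeat != 0:
        raise ValueError(
            f"target has {n_chains} chains, not divisible into repeats of "
            f"{chains_per_repeat} chains")
    n_repeats = n_chains // chains_per_repeat
    if n_repeats < 2:
        raise ValueError(f"need >= 2 repeats, got {n_repeats}")

    cfg1 = cfg1 or OptimizerConfig(population=50, generations=50)
    cfg2 = cfg2 or OptimizerConfig(population=40, generations=100,
                                   seed=cfg1.seed + 1)

    repeat_target = _slice_repeat(target, chains_per_repeat, 0)
    stage1 = StructureFit(repeat_target, "helix_pair",
                          ranges=unit_ranges).fit(cfg1)

    fixed = {"repeat_unit": stage1.best_model, "n_repeats": n_repeats}
    stage2 = StructureFit(target, "solenoid", fixed=fixed,
                          ranges=solenoid_ranges).fit(cfg2)
    stage2.stage1 = stage1
    return stage2
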