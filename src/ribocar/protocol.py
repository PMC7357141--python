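"""Staged minimization/heating/equilibration/production protocol as data.

The schedule reproduces the optimized restrained-subsystem protocol: eleven
minimization rounds ramping the positional restraint weight from 100 down
to 1 kcal/mol/Å² (each round restrained to the last structure of the
previous one), a 20 ps heating step at 2 fs with all residues restrained at
20 kcal/mol/Å², 3 ns of equilibration at 1 fs with inherited velocities,
then production at 300 K sampled at 100 frames/ns with only the onion shell
restrained.  The solvent environment (truncated octahedral box, 12 Å
margin, TIP3P water, Na+ counter-ions) is recorded as parameters — no MD
engine is run here; the schedule renders to generic JSON or AMBER
mdin-style input text.

The between-round energy-drop rule used to design the ramp (each round's
total energy drop smaller than the previous round's) needs engine energies
to evaluate, so it is carried as a documentation field, not enforced.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

__all__ = [
    "MinimizationRound",
    "HeatingStage",
    "EquilibrationStage",
    "ProductionStage",
    "Environment",
    "ProtocolSchedule",
    "default_schedule",
    "render_schedule",
    "parse_schedule",
    "DialectError",
]

ENERGY_DROP_NOTE = (
    "restraint-weight drops between rounds sized so each round's total "
    "energy drop is smaller than the previous round's, in the same or "
    "fewer steps; requires engine energies, recorded as design criterion")


class DialectError(ValueError):
    pass


@dataclass(frozen=True)
class MinimizationRound:
    total_steps: int
    steepest_descent_steps: int
    restraint_weight: float  # kcal/mol/A^2

    def __post_init__(self) -> None:
        if not 0 < self.steepest_descent_steps <= self.total_steps:
            raise ValueError(
                "steepest-descent steps must be in (0, total_steps]")
        if not self.restraint_weight > 0:
            raise ValueError("restraint weight must be positive")


@dataclass(frozen=True)
class HeatingStage:
    duration_ps: float = 20.0
    timestep_fs: float = 2.0
    restraint_weight: float = 20.0


@dataclass(frozen=True)
class EquilibrationStage:
    duration_ns: float = 3.0
    timestep_fs: float = 1.0
    restraint_weight: float = 20.0
    inherit_velocities: bool = True


@dataclass(frozen=True)
class ProductionStage:
    frames_per_ns: float = 100.0
    temperature_K: float = 300.0
    timestep_fs: float = 2.0
    duration_ns: float | None = None  # per-run choice, not fixed by protocol
    onion_mask: str = ":onion_shell"
    onion_weight: float = 20.0
    # optional stabilization: short unrestrained MD before fixing the shell
    pre_restraint_md_ps: int = 0

    def __post_init__(self) -> None:
        if self.pre_restraint_md_ps not in (0, 10, 100):
            raise ValueError("pre_restraint_md_ps must be 0, 10 or 100")


@dataclass(frozen=True)
class Environment:
    box: str = "truncated_octahedron"
    solvent_margin_A: float = 12.0
    water_model: str = "TIP3P"
    counter_ion: str = "Na+"


@dataclass(frozen=True)
class ProtocolSchedule:
    rounds: tuple[MinimizationRound, ...]
    heating: HeatingStage
    equilibration: EquilibrationStage
    production: ProductionStage
    environment: Environment
    energy_drop_note: str = ENERGY_DROP_NOTE

    def __post_init__(self) -> None:
        if not self.rounds:
            raise ValueError("schedule needs at least one minimization round")
        weights = [r.restraint_weight for r in self.rounds]
        if any(b > a for a, b in zip(weights, weights[1:])):
            raise ValueError("restraint weights must be non-increasing")


_PRINTED_ROUNDS = (
    (20000, 2500, 100.0),
    (10000, 2500, 75.0),
    (5000, 2500, 65.0),
    (3000, 2500, 55.0),
    (3000, 2500, 45.0),
    (2000, 2000, 30.0),
    (2000, 2000, 20.0),
    (2000, 2000, 15.0),
    (2000, 2000, 10.0),
    (2000, 2000, 5.0),
    (2000, 2000, 1.0),
)


def default_schedule() -> ProtocolSchedule:
    """The full published protocol as a constant: two calls are identical."""
    return ProtocolSchedule(
        rounds=tuple(MinimizationRound(*r) for r in _PRINTED_ROUNDS),
        heating=HeatingStage(),
        equilibration=EquilibrationStage(),
        production=ProductionStage(),
        environment=Environment(),
    )


# -- rendering -------------------------------------------------------------

def _json_docs(p: ProtocolSchedule) -> list[tuple[str, str]]:
    docs: list[tuple[str, str]] = []
    for i, r in enumerate(p.rounds, start=1):
        docs.append((f"min_{i:02d}.json", json.dumps(
            {"stage": "minimization", "round": i, **asdict(r)}, indent=1)))
    docs.append(("heating.json", json.dumps(
        {"stage": "heating", **asdict(p.heating)}, indent=1)))
    docs.append(("equilibration.json", json.dumps(
        {"stage": "equilibration", **asdict(p.equilibration)}, indent=1)))
    docs.append(("production.json", json.dumps(
        {"stage": "production", **asdict(p.production),
         "environment": asdict(p.environment),
         "energy_drop_note": p.energy_drop_note}, indent=1)))
    return docs


def _mdin_minimization(i: int, r: MinimizationRound, mask: str) -> str:
    return (
        f"Minimization round {i}: restraint {r.restraint_weight:g} "
        "kcal/mol/A^2\n"
        " &cntrl\n"
        f"  imin=1, maxcyc={r.total_steps}, ncyc={r.steepest_descent_steps},\n"
        f"  ntr=1, restraint_wt={r.restraint_weight:.1f},\n"
        f"  restraintmask='{mask}',\n"
        " /\n")


def _mdin_docs(p: ProtocolSchedule) -> list[tuple[str, str]]:
    all_mask = ":*"
    docs = [(f"min_{i:02d}.mdin", _mdin_minimization(i, r, all_mask))
            for i, r in enumerate(p.rounds, start=1)]
    h = p.heating
    dt_ps = h.timestep_fs / 1000.0
    docs.append(("heating.mdin", (
        f"Heating to {p.production.temperature_K:g} K over "
        f"{h.duration_ps:g} ps\n"
        " &cntrl\n"
        f"  imin=0, irest=0, ntx=1,\n"
        f"  nstlim={int(round(h.duration_ps / dt_ps))}, dt={dt_ps:.3f},\n"
        f"  tempi=0.0, temp0={p.production.temperature_K:.1f}, ntt=1,\n"
        f"  ntr=1, restraint_wt={h.restraint_weight:.1f},\n"
        f"  restraintmask='{all_mask}',\n"
        " /\n")))
    e = p.equilibration
    dt_ps = e.timestep_fs / 1000.0
    docs.append(("equilibration.mdin", (
        f"Equilibration {e.duration_ns:g} ns"
        f"{', inherited velocities' if e.inherit_velocities else ''}\n"
        " &cntrl\n"
        f"  imin=0, irest={int(e.inherit_velocities)}, "
        f"ntx={5 if e.inherit_velocities else 1},\n"
        f"  nstlim={int(round(e.duration_ns * 1000.0 / dt_ps))}, "
        f"dt={dt_ps:.3f},\n"
        f"  temp0={p.production.temperature_K:.1f}, ntt=1,\n"
        f"  ntr=1, restraint_wt={e.restraint_weight:.1f},\n"
        f"  restraintmask='{all_mask}',\n"
        " /\n")))
    prod = p.production
    dt_ps = prod.timestep_fs / 1000.0
    ntwx = int(round(1000.0 / (prod.frames_per_ns * dt_ps)))
    nstlim = (int(round(prod.duration_ns * 1000.0 / dt_ps))
              if prod.duration_ns else 0)
    docs.append(("production.mdin", (
        f"Production at {prod.temperature_K:g} K, "
        f"{prod.frames_per_ns:g} frames/ns, onion shell restrained\n"
        " &cntrl\n"
        f"  imin=0, irest=1, ntx=5,\n"
        f"  nstlim={nstlim}, dt={dt_ps:.3f}, ntwx={ntwx},\n"
        f"  temp0={prod.temperature_K:.1f}, ntt=1,\n"
        f"  ntr=1, restraint_wt={prod.onion_weight:.1f},\n"
        f"  restraintmask='{prod.onion_mask}',\n"
        " /\n")))
    return docs


def render_schedule(p: ProtocolSchedule,
                    dialect: str = "generic_json") -> list[tuple[str, str]]:
    """Render a schedule to text documents, one per stage.

    ``generic_json`` round-trips exactly through :func:`parse_schedule`;
    ``amber_mdin`` emits mdin-style input text with ntr/restraint_wt lines.
    Returns ``(document name, text)`` pairs.
    """
    if dialect == "generic_json":
        return _json_docs(p)
    if dialect == "amber_mdin":
        return _mdin_docs(p)
    raise DialectError(f"unknown dialect {dialect!r}")


def parse_schedule(docs: list[tuple[str, str]]) -> ProtocolSchedule:
    """Rebuild a schedule from its generic_json rendering."""
    rounds: list[tuple[int, MinimizationRound]] = []
    heating = equilibration = production = environment = None
    note = ENERGY_DROP_NOTE
    for _, text in docs:
        d = json.loads(text)
        stage = d.pop("stage")
        if stage == "minimization":
            i = d.pop("round")
            rounds.append((i, MinimizationRound(**d)))
        elif stage == "heating":
            heating = HeatingStage(**d)
        elif stage == "equilibration":
            equilibration = EquilibrationStage(**d)
        elif stage == "production":
            environment = Environment(**d.pop("environment"))
            note = d.pop("energy_drop_note")
            production = ProductionStage(**d)
        else:
            raise DialectError(f"unknown stage {stage!r}")
    if None in (heating, equilibration, production, environment):
        raise DialectError("incomplete schedule document set")
    rounds.sort(key=lambda t: t[0])
    return ProtocolSchedule(tuple(r for _, r in rounds), heating,
                            equilibration, production, environment, note)
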