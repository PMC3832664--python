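"""Independent oracles for the simulator and statistics tests.

The deterministic lineage oracle enumerates the cv=0 division schedule with
plain while-loops — deliberately sharing no code with the package's
event-driven simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class OracleCell:
    ctype: str
    birth: float
    nebds: list[float] = field(default_factory=list)
    terminal: bool = False  # divides once and is then replaced by daughters


def enumerate_deterministic(
    mode: str,
    duration: float,
    nb_cycle: float,
    gmc_delay: float,
    inp_first: float,
    inp_mature: float,
    mitosis: float,
    initial_phase: float = 0.0,
) -> list[OracleCell]:
    """All cells and NEBD events of a cv=0 lineage within ``duration``."""
    cells: list[OracleCell] = []
    root = OracleCell("NB", 0.0)
    cells.append(root)

    def add_gmc(birth: float) -> None:
        gmc = OracleCell("GMC", birth, terminal=True)
        cells.append(gmc)
        nebd = birth + gmc_delay
        if nebd <= duration:
            gmc.nebds.append(nebd)
            if nebd + mitosis < duration:
                cells.append(OracleCell("NEURON", nebd + mitosis))
                cells.append(OracleCell("NEURON", nebd + mitosis))

    def add_inp(birth: float) -> None:
        inp = OracleCell("INP", birth)
        cells.append(inp)
        nebd = birth + inp_first
        while nebd <= duration:
            inp.nebds.append(nebd)
            if nebd + mitosis < duration:
                add_gmc(nebd + mitosis)
            nebd = nebd + inp_mature

    t = nb_cycle * (1.0 - initial_phase)
    while t <= duration:
        root.nebds.append(t)
        birth = t + mitosis
        if birth < duration:
            if mode == "typeI":
                add_gmc(birth)
            else:
                add_inp(birth)
        t += nb_cycle
    return cells


def alive_at(cell: OracleCell, t: float, mitosis: float) -> bool:
    """Alive = born, and (for terminal cells) daughters not yet appeared."""
    if t < cell.birth:
        return False
    if cell.terminal and cell.nebds and t >= cell.nebds[0] + mitosis:
        return False
    return True


def census_at(cells: list[OracleCell], t: float, mitosis: float) -> int:
    return sum(1 for c in cells if alive_at(c, t, mitosis))


def count_nebd_events(cells: list[OracleCell]) -> int:
    return sum(len(c.nebds) for c in cells)
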