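"""Global phasing: switch errors and phase blocks over superclusters.

Local phase is enforced within superclusters, but the truth-to-query
haplotype mapping may flip between superclusters (a switch error).  Each
supercluster carries a category -- X (parallel mapping), Y (crossed) or
uncategorized (both mappings tie) -- and a two-state dynamic program
chooses a global phase-state path minimizing the weighted sum of switch
errors (state changes between adjacent superclusters) and supercluster
phasing errors (a categorized supercluster whose category disagrees with
the block state).  Uncategorized superclusters cost nothing in either
state.  Phasing never alters variant credit totals; it is reported
separately.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class PhaseBlock:
    """Maximal run of superclusters assigned one phase state."""

    contig: str
    state: str            # 'X' or 'Y'
    start_index: int      # first supercluster index in the block
    end_index: int        # one past the last supercluster index
    n_phase_errors: int = 0


def phase_forward_backward(categories: list[str | None],
                           switch_cost: float = 1.0,
                           phase_error_cost: float = 1.0,
                           contig: str = "") -> tuple[list[PhaseBlock], int, int]:
    """Minimal-cost phase-state path over one contig's superclusters.

    Returns (blocks, switch_errors, phasing_errors).  Ties prefer fewer
    switches (longer blocks); the first block's state ties toward X.
    """
    n = len(categories)
    if n == 0:
        return [], 0, 0
    INF = float("inf")
    # forward costs per state, with switch counts as secondary tie-break
    cost = {"X": 0.0, "Y": 0.0}
    switches = {"X": 0, "Y": 0}
    back: list[dict[str, str]] = []
    for i, cat in enumerate(categories):
        err = {s: (phase_error_cost if cat is not None and cat != s else 0.0)
               for s in "XY"}
        new_cost: dict[str, float] = {}
        new_sw: dict[str, int] = {}
        choice: dict[str, str] = {}
        for s in "XY":
            other = "Y" if s == "X" else "X"
            stay = (cost[s], switches[s])
            move = (cost[other] + switch_cost, switches[other] + 1)
            if i == 0:
                stay, move = (0.0, 0), (INF, 0)
            if move < stay:
                new_cost[s], new_sw[s] = move[0] + err[s], move[1]
                choice[s] = other
            else:
                new_cost[s], new_sw[s] = stay[0] + err[s], stay[1]
                choice[s] = s
        back.append(choice)
        cost, switches = new_cost, new_sw

    # backward pass: recover the state path
    final = "X" if (cost["X"], switches["X"]) <= (cost["Y"], switches["Y"]) else "Y"
    states = [final]
    for i in range(n - 1, 0, -1):
        states.append(back[i][states[-1]])
    states.reverse()

    blocks: list[PhaseBlock] = []
    phasing_errors = 0
    for i, (s, cat) in enumerate(zip(states, categories)):
        if not blocks or blocks[-1].state != s:
            blocks.append(PhaseBlock(contig, s, i, i + 1))
        else:
            blocks[-1].end_index = i + 1
        if cat is not None and cat != s:
            blocks[-1].n_phase_errors += 1
            phasing_errors += 1
    return blocks, count_switch_errors(blocks), phasing_errors


def count_switch_errors(blocks: list[PhaseBlock]) -> int:
    """Block boundaries within each contig (never across contigs)."""
    per_contig: dict[str, int] = {}
    for b in blocks:
        per_contig[b.contig] = per_contig.get(b.contig, 0) + 1
    return sum(n - 1 for n in per_contig.values() if n > 0)
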