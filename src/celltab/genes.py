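"""Stochastic gene-expression module: telegraph switching + mRNA birth/death.

Each gene has ``copy_number`` independent copies switching between an
inactive and an active state with first-order rates (the telegraph model).
Active copies transcribe; transcripts degrade first-order.  Over one
exchange window of length ``dt`` (30 s by default) the module tau-leaps
with rates frozen at the window start:

* each inactive copy activates with probability ``1 - exp(-k_act dt)`` and
  each active copy inactivates with probability ``1 - exp(-k_inact dt)``
  (at most one switch per copy per window);
* mRNA births are Poisson(``active * rate_per_copy * dt``) and deaths
  Poisson(``k_deg * count * dt``), with deaths truncated so counts never go
  negative.

The transcription rate per active copy is modulated by regulator protein
concentrations evaluated at the window start:

    rate = (k_const + k_max * u) * w
    u = A / (1 + A),   A = sum_activators (x/B)^a        (u = 0 if none)
    w = prod_repressors 1 / (1 + (x/B)^|a|)              (w = 1 if none)

so the rate reduces to ``k_const`` with no regulators and saturates at
``(k_const + k_max)`` under full activation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly import GeneBundle
from .errors import SimulationError

__all__ = [
    "GeneState",
    "N_AVOGADRO",
    "initial_gene_state",
    "regulation_factor",
    "effective_transcription_rates",
    "step_gene_states",
    "step_mrna_counts",
    "expected_window_update",
    "mpc_to_nM",
    "nM_to_mpc",
]

N_AVOGADRO = 6.02214076e23


@dataclass
class GeneState:
    """Per-gene active copy counts and integer mRNA copy numbers."""

    active: np.ndarray  # int, in [0, copy_number]
    mrna: np.ndarray    # int, >= 0

    def copy(self) -> "GeneState":
        return GeneState(self.active.copy(), self.mrna.copy())


def mpc_to_nM(count, volume_L: float):
    """Molecules-per-cell to nM in a compartment of ``volume_L`` liters."""
    if volume_L <= 0:
        raise SimulationError(f"non-positive compartment volume {volume_L}")
    return np.asarray(count, float) / (N_AVOGADRO * volume_L) * 1e9


def nM_to_mpc(conc, volume_L: float, integer: bool = False):
    """Inverse of :func:`mpc_to_nM`; rounds to nearest integer when asked
    (stochastic state), exact real otherwise (reporting)."""
    if volume_L <= 0:
        raise SimulationError(f"non-positive compartment volume {volume_L}")
    mpc = np.asarray(conc, float) * (N_AVOGADRO * volume_L) / 1e9
    if integer:
        return np.rint(mpc).astype(np.int64)
    return mpc


def regulation_factor(entries, concentrations) -> tuple[float, float]:
    """Activation/repression multipliers for one gene.

    ``entries`` is a sequence of ``(species_index, hill, half_max_nM)``
    (signed Hill coefficient); ``concentrations`` the nM state vector.
    Returns ``(u, w)`` as defined in the module docstring.
    """
    act = 0.0
    w = 1.0
    for idx, hill, half_max in entries:
        x = max(float(concentrations[idx]), 0.0)
        term = (x / half_max) ** abs(hill)
        if hill > 0:
            act += term
        else:
            w *= 1.0 / (1.0 + term)
    u = act / (1.0 + act) if act > 0 else 0.0
    return u, w


def effective_transcription_rates(bundle: GeneBundle, concentrations) -> np.ndarray:
    """Transcription rate per active copy (mpc/s) for every gene, with
    regulation evaluated at the given concentrations."""
    rates = np.empty(bundle.n_genes)
    for g, gene in enumerate(bundle.genes):
        u, w = regulation_factor(bundle.regulation[g], concentrations)
        rates[g] = (gene.k_transcription_const + gene.k_transcription_max * u) * w
    return rates


def initial_gene_state(bundle: GeneBundle, rng: np.random.Generator | None = None,
                       deterministic: bool = False) -> GeneState:
    """Window-zero state: mRNA counts from the omics file; active copies
    sampled from the telegraph stationary law (or its mean when
    ``deterministic``)."""
    n = bundle.n_genes
    mrna = np.array([np.rint(g.mrna_mpc) for g in bundle.genes], dtype=np.int64)
    active = np.empty(n, dtype=np.int64)
    for g, gene in enumerate(bundle.genes):
        tot = gene.k_activation + gene.k_inactivation
        f = gene.k_activation / tot if tot > 0 else 0.0
        if deterministic or rng is None:
            active[g] = int(np.rint(gene.copy_number * f))
        else:
            active[g] = rng.binomial(gene.copy_number, f)
    return GeneState(active=active, mrna=mrna)


def step_gene_states(state: GeneState, bundle: GeneBundle, dt: float,
                     rng: np.random.Generator) -> GeneState:
    """One tau-leap window of telegraph switching (copies independent)."""
    if dt < 0:
        raise SimulationError("dt must be >= 0")
    active = state.active.copy()
    for g, gene in enumerate(bundle.genes):
        n_act = int(active[g])
        n_inact = gene.copy_number - n_act
        p_on = -np.expm1(-gene.k_activation * dt)
        p_off = -np.expm1(-gene.k_inactivation * dt)
        gains = rng.binomial(n_inact, p_on) if n_inact > 0 else 0
        losses = rng.binomial(n_act, p_off) if n_act > 0 else 0
        active[g] = n_act + gains - losses
    return GeneState(active=active, mrna=state.mrna.copy())


def step_mrna_counts(state: GeneState, bundle: GeneBundle,
                     rates_per_copy: np.ndarray, dt: float,
                     rng: np.random.Generator) -> GeneState:
    """One tau-leap window of mRNA birth/death; deaths truncated at zero."""
    if dt < 0:
        raise SimulationError("dt must be >= 0")
    mrna = state.mrna.copy()
    for g, gene in enumerate(bundle.genes):
        births = rng.poisson(state.active[g] * rates_per_copy[g] * dt)
        deaths = rng.poisson(gene.k_mrna_degradation * mrna[g] * dt)
        mrna[g] = max(int(mrna[g]) + int(births) - int(deaths), 0)
    return GeneState(active=state.active.copy(), mrna=mrna)


def expected_window_update(mrna: np.ndarray, bundle: GeneBundle,
                           rates_per_copy: np.ndarray, dt: float) -> np.ndarray:
    """Deterministic-mode transcript update over one window:

        m <- m + dt * (n f_active r - k_deg m),
        f_active = k_act / (k_act + k_inact)

    This is exactly the expected value of the tau-leap birth/death step, so
    the deterministic trajectory is the mean-field limit of the hybrid one
    on the same window grid; its fixed point is the analytic stationary
    mean ``n f r / k_deg``.  ``mrna`` is real-valued mpc."""
    out = np.asarray(mrna, float).copy()
    for g, gene in enumerate(bundle.genes):
        tot = gene.k_activation + gene.k_inactivation
        f = gene.k_activation / tot if tot > 0 else 0.0
        production = gene.copy_number * f * rates_per_copy[g]
        out[g] = out[g] + dt * (production - gene.k_mrna_degradation * out[g])
    return out
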