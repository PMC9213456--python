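"""Independent hand-assembled reference implementations used as oracles.

Everything here is computed directly from the parsed input files with plain
Python loops and ``eval`` on the formula strings — no sympy, no compiled
model — so it is an independent route against which the compiler's RHS is
checked.
"""

from __future__ import annotations

import numpy as np

from celltab.model_io import ModelInputSet


def oracle_rates(m: ModelInputSet, state: np.ndarray) -> np.ndarray:
    """Per-reaction rates v_j (nM/s in the reaction compartment)."""
    volumes = m.compartment_volumes
    sp_names = m.species_names
    comp_of = {s.name: s.compartment for s in m.species}
    smat = m.stoichiometry
    env0 = {name: float(state[i]) for i, name in enumerate(sp_names)}
    v = np.empty(len(m.reactions))
    for j, r in enumerate(m.reactions):
        v_rxn = volumes[r.compartment]
        if r.is_mass_action:
            rate = r.rate_constant
            col = smat.iloc[:, j]
            for name in sp_names:
                coeff = int(col[name])
                if coeff < 0:
                    corrected = env0[name] * volumes[comp_of[name]] / v_rxn
                    rate *= corrected ** (-coeff)
            v[j] = rate
        else:
            env = dict(env0)
            env.update({p: val for p, val in r.local_parameters})
            v[j] = eval(r.formula, {"__builtins__": {}}, env)  # noqa: S307
    return v


def oracle_rhs(m: ModelInputSet, state: np.ndarray) -> np.ndarray:
    """d(state)/dt by brute-force per-reaction summation."""
    volumes = m.compartment_volumes
    comp_of = {s.name: s.compartment for s in m.species}
    v = oracle_rates(m, state)
    smat = m.stoichiometry.to_numpy(dtype=float)
    out = np.zeros(len(m.species))
    for i, s in enumerate(m.species):
        for j, r in enumerate(m.reactions):
            if smat[i, j]:
                out[i] += smat[i, j] * v[j] * volumes[r.compartment] \
                    / volumes[comp_of[s.name]]
    return out
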