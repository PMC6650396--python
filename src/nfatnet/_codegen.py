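"""Compile a :class:`NetworkModel` into a fast ODE right-hand side.

The reaction list is the single source of truth: this module unrolls every
rate law into one generated Python function ``rhs(t, y, p, u)`` (state ``y``
in nM, parameter vector ``p`` ordered as ``model.parameter_names``, constant
stimulus multiplier ``u`` for the current protocol segment) and applies the
stoichiometry. The generated function is JIT-compiled with numba when
available, which matters for the sampling-heavy analyses; the pure-Python
fall-back is numerically identical.

Species concentrations are clamped at zero inside rate expressions so that
tiny negative excursions of the stiff integrator cannot produce negative
rates or NaNs in fractional-power Hill terms.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .network import LawForm, NetworkModel

try:  # pragma: no cover - exercised implicitly everywhere
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _expr(model: NetworkModel, rxn, pidx: dict[str, int]) -> str:
    """Python expression string for one reaction rate."""

    def P(role: str) -> str:
        return f"p[{pidx[rxn.law.params[role]]}]"

    def S(name: str) -> str:
        return f"s{model.species_index(name)}"

    law = rxn.law
    if law.form is LawForm.MASS_ACTION:
        parts = [P("k")]
        for sp, st in rxn.substrates:
            parts += [S(sp)] * st
        e = "*".join(parts)
    elif law.form is LawForm.MICHAELIS_MENTEN:
        (sub, _), = rxn.substrates
        vmax = (
            f"p[{pidx[law.params['kc']]}]*{S(rxn.enzyme)}"
            if "kc" in law.params
            else f"p[{pidx[law.params['Vmax']]}]"
        )
        e = f"{vmax}*{S(sub)}/({P('Km')}+{S(sub)})"
    else:  # HILL
        s = S(rxn.regulator)
        n = law.hill_n
        sn = f"{s}**{n}" if n != 1 else s
        kn = f"{P('Km')}**{n}" if n != 1 else P("Km")
        e = f"{P('Vmax')}*{sn}/({kn}+{sn})"
        if "basal" in law.params:
            e = f"({e}+p[{pidx[law.params['basal']]}])"
    for sp, kname in rxn.activators:
        e += f"*{S(sp)}/(p[{pidx[kname]}]+{S(sp)})"
    for sp, kname in rxn.enhancers:
        e += f"*(1.0+{S(sp)}/p[{pidx[kname]}])"
    for sp, kname in rxn.inhibitors:
        e += f"/(1.0+p[{pidx[kname]}]*{S(sp)})"
    if rxn.driven_by_input:
        e = f"u*{e}"
    return e


def generate_rhs_source(model: NetworkModel, fname: str = "rhs") -> str:
    pidx = {n: i for i, n in enumerate(model.parameter_names)}
    nsp = len(model.species)
    lines = [f"def {fname}(t, y, p, u):"]
    used = {model.species_index(s) for r in model.reactions for s in r.species_names()}
    for i in sorted(used):
        lines.append(f"    s{i} = y[{i}] if y[{i}] > 0.0 else 0.0")
    terms: dict[int, list[str]] = {i: [] for i in range(nsp)}
    for k, rxn in enumerate(model.reactions):
        lines.append(f"    v{k} = {_expr(model, rxn, pidx)}")
        for sp, st in rxn.substrates:
            terms[model.species_index(sp)].append(f"-{st}*v{k}" if st != 1 else f"-v{k}")
        for sp, st in rxn.products:
            terms[model.species_index(sp)].append(f"+{st}*v{k}" if st != 1 else f"+v{k}")
    lines.append(f"    dy = np.empty({nsp})")
    for i in range(nsp):
        lines.append(f"    dy[{i}] = {''.join(terms[i]) or '0.0'}")
    lines.append("    return dy")
    return "\n".join(lines)


@lru_cache(maxsize=64)
def _compile_for(key: tuple, source: str):
    ns: dict = {"np": np}
    exec(source, ns)  # noqa: S102 - source generated above from typed reactions
    fn = ns["rhs"]
    if _HAVE_NUMBA:
        try:
            fn = numba.njit(fn, cache=False)
        except Exception:  # pragma: no cover - numba regression safety net
            fn = ns["rhs"]
    return fn


def compile_rhs(model: NetworkModel):
    """Return ``rhs(t, y, p, u) -> dy`` for the model (cached per structure)."""
    source = generate_rhs_source(model)
    key = (model.name, hash(source))
    return _compile_for(key, source)


@lru_cache(maxsize=64)
def _jac_for(key: tuple, source: str, n: int):
    ns: dict = {"np": np}
    exec(source, ns)  # noqa: S102
    rhs = ns["rhs"]
    if not _HAVE_NUMBA:
        return None
    try:
        rhs = numba.njit(rhs, cache=False)

        @numba.njit(cache=False)
        def jac(t, y, p, u):
            f0 = rhs(t, y, p, u)
            J = np.empty((n, n))
            for j in range(n):
                yj = y[j]
                h = 1e-7 * abs(yj) + 1e-10
                y[j] = yj + h
                f1 = rhs(t, y, p, u)
                y[j] = yj
                for i in range(n):
                    J[i, j] = (f1[i] - f0[i]) / h
            return J

        return jac
    except Exception:  # pragma: no cover
        return None


def compile_jac(model: NetworkModel):
    """Finite-difference Jacobian evaluated entirely inside compiled code.

    Supplying it to LSODA avoids one Python callback per state dimension
    per Jacobian update, which dominates the cost of stiff steps. Returns
    None when numba is unavailable (the integrator's internal differencing
    is then no slower).
    """
    source = generate_rhs_source(model)
    key = (model.name, hash(source), "jac")
    return _jac_for(key, source, len(model.species))
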