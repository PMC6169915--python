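"""Optional CellML interchange adapter.

Reads and writes a pragmatic subset of CellML 2.0: a single component whose
variables carry ``initial_value`` attributes and whose mathematics is content
MathML (algebraic assignments and first-order ODEs in one independent
variable).  That subset covers Hodgkin-Huxley-style single-cell models —
variables, parameters, gating/current expressions and state ODEs — which is
what the calibration pipeline consumes.

Loaded models satisfy the :class:`~iontune.models.IonicModel` contract: the
MathML is parsed to sympy expressions, algebraic variables are substituted
into the ODE right-hand sides, and the result is lambdified.  A user-supplied
name map assigns model variables to the canonical current slots so the
potassium bookkeeping applies unchanged; the [K+]i-dynamics augmentation can
be switched on for models that carry potassium as a constant parameter.

The adapter depends only on lxml and sympy; the rest of the package does not
import it.
"""

from __future__ import annotations

import numpy as np
import sympy as sp
from lxml import etree

from .models import CurrentsRecord, IonicModel, ik_tot

__all__ = ["load_cellml_model", "export_cellml", "CellMLModel",
           "CellMLError", "toy_symbolic_equations"]

CELLML_NS = "http://www.cellml.org/cellml/2.0#"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


class CellMLError(ValueError):
    """Unparseable file or incomplete current mapping."""


# --------------------------------------------------------------------------
# content-MathML <-> sympy
# --------------------------------------------------------------------------

def _tag(el):
    return etree.QName(el).localname


def _mathml_to_sympy(el, symbols):
    t = _tag(el)
    if t == "ci":
        name = el.text.strip()
        return symbols.setdefault(name, sp.Symbol(name))
    if t == "cn":
        return sp.Float(el.text.strip())
    if t == "apply":
        children = [c for c in el if isinstance(c.tag, str)]
        op = _tag(children[0])
        args = children[1:]
        if op == "diff":
            bvar = [c for c in args if _tag(c) == "bvar"][0]
            wrt = _mathml_to_sympy([c for c in bvar if isinstance(c.tag, str)][0],
                                   symbols)
            target = [c for c in args if _tag(c) != "bvar"][0]
            return sp.Derivative(_mathml_to_sympy(target, symbols), wrt)
        sub = [_mathml_to_sympy(a, symbols) for a in args]
        if op == "eq":
            return sp.Eq(sub[0], sub[1])
        if op == "plus":
            return sp.Add(*sub)
        if op == "times":
            return sp.Mul(*sub)
        if op == "minus":
            return -sub[0] if len(sub) == 1 else sub[0] - sub[1]
        if op == "divide":
            return sub[0] / sub[1]
        if op == "power":
            return sub[0] ** sub[1]
        if op == "exp":
            return sp.exp(sub[0])
        if op == "ln":
            return sp.log(sub[0])
        if op == "abs":
            return sp.Abs(sub[0])
        raise CellMLError(f"unsupported MathML operator <{op}>")
    raise CellMLError(f"unsupported MathML element <{t}>")


def _sympy_to_mathml(expr, M):
    """Emit a content-MathML element for a sympy expression (the inverse
    subset of :func:`_mathml_to_sympy`)."""
    def build(parent, e):
        if isinstance(e, sp.Symbol):
            el = etree.SubElement(parent, f"{{{MATHML_NS}}}ci")
            el.text = e.name
        elif e.is_Number:
            el = etree.SubElement(parent, f"{{{MATHML_NS}}}cn")
            el.text = repr(float(e))
        elif isinstance(e, sp.Add):
            ap = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
            etree.SubElement(ap, f"{{{MATHML_NS}}}plus")
            for a in e.args:
                build(ap, a)
        elif isinstance(e, sp.Mul):
            ap = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
            etree.SubElement(ap, f"{{{MATHML_NS}}}times")
            for a in e.args:
                build(ap, a)
        elif isinstance(e, sp.Pow):
            ap = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
            etree.SubElement(ap, f"{{{MATHML_NS}}}power")
            build(ap, e.base)
            build(ap, e.exp)
        elif isinstance(e, sp.exp):
            ap = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
            etree.SubElement(ap, f"{{{MATHML_NS}}}exp")
            build(ap, e.args[0])
        elif isinstance(e, sp.log):
            ap = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
            etree.SubElement(ap, f"{{{MATHML_NS}}}ln")
            build(ap, e.args[0])
        else:
            raise CellMLError(f"cannot serialize expression node {e!r}")

    build(M, expr)


# --------------------------------------------------------------------------
# loading
# --------------------------------------------------------------------------

class CellMLModel(IonicModel):
    """Ionic model backed by parsed CellML equations.

    ``current_map`` maps model variable names onto
    :class:`~iontune.models.CurrentsRecord` slots.  The stimulus enters
    through the model variable named ``stimulus_var`` (default ``Istim``),
    which is overridden at integration time.
    """

    def __init__(self, states, odes, algebraic, params, units, inits,
                 time_var="t", current_map=None, stimulus_var="Istim",
                 name="cellml"):
        super().__init__()
        self.name = name
        self._time = sp.Symbol(time_var)
        self._state_syms = [sp.Symbol(s) for s in states]
        self._odes = dict(odes)            # state name -> expr
        self._algebraic = dict(algebraic)  # var name -> expr (substituted)
        self.params = dict(params)
        self._units = dict(units)
        self._state_inits = dict(inits)    # state name -> initial value
        self.current_map = dict(current_map or {})
        self.stimulus_var = stimulus_var
        self._compile()

    @property
    def state_names(self):
        return tuple(str(s) for s in self._state_syms)

    @property
    def state_units(self):
        return tuple(self._units.get(s, "1") for s in self.state_names)

    @property
    def initial_state(self):
        return np.array([self._state_inits[s] for s in self.state_names])

    def _compile(self):
        psyms = [sp.Symbol(p) for p in self.params]
        stim = sp.Symbol(self.stimulus_var)
        args = [self._time, *self._state_syms, *psyms, stim]
        exprs = [self._odes[s] for s in self.state_names]
        self._rhs_fn = sp.lambdify(args, exprs, modules="numpy")
        self._current_fns = {
            slot: sp.lambdify(args, self._algebraic[var], modules="numpy")
            for var, slot in self.current_map.items()}
        self._param_order = list(self.params)

    def __deepcopy__(self, memo):
        # lambdified functions are stateless; shallow-copy them
        new = object.__new__(type(self))
        new.__dict__.update(self.__dict__)
        for attr in ("params", "_state_inits", "_odes", "_algebraic",
                     "_units", "current_map"):
            setattr(new, attr, dict(getattr(self, attr)))
        new._state_syms = list(self._state_syms)
        memo[id(self)] = new
        return new

    def _argvec(self, t, y, istim):
        return [t, *y, *[self.params[p] for p in self._param_order], istim]

    def _currents(self, t, y, istim) -> CurrentsRecord:
        a = self._argvec(t, y, istim)
        vals = {slot: fn(*a) for slot, fn in self._current_fns.items()}
        vals["Istim"] = istim if "Istim" not in vals else vals["Istim"]
        return CurrentsRecord(**vals)

    def rhs(self, t, y, istim=0.0):
        dy = np.asarray(self._rhs_fn(*self._argvec(t, y, istim)), dtype=float)
        return dy, self._currents(t, y, istim)

    def currents_series(self, t, Y, istim) -> CurrentsRecord:
        args = [t] + [Y[:, i] for i in range(Y.shape[1])] \
            + [self.params[p] for p in self._param_order] + [istim]
        vals = {slot: np.broadcast_to(fn(*args), t.shape).astype(float)
                for slot, fn in self._current_fns.items()}
        if "Istim" not in vals:
            vals["Istim"] = np.asarray(istim, dtype=float)
        return CurrentsRecord(**vals)

    # -- [K+]i-dynamics augmentation ------------------------------------
    def augment_potassium_dynamics(self, ki_param="Ki",
                                   kappa: float | None = None) -> "CellMLModel":
        """Promote a constant-[K+]i parameter to a dynamic state.

        Adds d[K+]i/dt = -kappa * I_K,tot built from the mapped current
        variables (kappa defaults to Cmem / (Vmyo * Frdy) when the model
        declares those constants).  Requires the current map to cover INaK —
        without the pump the potassium budget is wrong by construction.
        """
        if ki_param not in self.params:
            raise CellMLError(f"no constant parameter {ki_param!r} to promote")
        required = {"INaK"}
        missing = required - set(self.current_map.values())
        if missing:
            raise CellMLError(
                f"current map missing {sorted(missing)}; the potassium "
                "budget needs the Na/K pump current")
        if kappa is None:
            try:
                kappa = self.params["Cmem"] / (self.params["Vmyo"]
                                               * self.params["Frdy"])
            except KeyError as exc:
                raise CellMLError(
                    "kappa not given and Cmem/Vmyo/Frdy not declared") from exc
        new = self.copy()
        ki = sp.Symbol(ki_param)
        k_slots = {"Ito", "IKr", "IKs", "IK1", "ICaK", "IKp"}
        expr = sp.Integer(0)
        inv = {slot: var for var, slot in new.current_map.items()}
        for slot, var in inv.items():
            if slot in k_slots:
                expr = expr + new._algebraic[var]
            elif slot == "INaK":
                expr = expr - 2 * new._algebraic[var]
        expr = expr + sp.Symbol(new.stimulus_var)
        init = new.params.pop(ki_param)
        new._state_syms = new._state_syms + [ki]
        new._odes[ki_param] = -sp.Float(kappa) * expr
        new._state_inits = dict(new._state_inits)
        new._state_inits[ki_param] = init
        new._units[ki_param] = new._units.get(ki_param, "mM")
        new._compile()
        return new


def load_cellml_model(path, current_map=None, stimulus_var="Istim",
                      name=None) -> CellMLModel:
    """Parse a CellML file into an :class:`IonicModel`.

    Variables with an ODE become states, variables defined by an algebraic
    equation are substituted into the right-hand sides, and variables with an
    ``initial_value`` but no equation become parameters.  ``current_map``
    maps model variable names to canonical current slots (e.g.
    ``{"I_K1": "IK1", "I_NaK": "INaK"}``).
    """
    try:
        tree = etree.parse(str(path))
    except (OSError, etree.XMLSyntaxError) as exc:
        raise CellMLError(f"cannot parse CellML file {path}: {exc}") from exc
    root = tree.getroot()
    variables = {}
    units = {}
    for var in root.iter(f"{{{CELLML_NS}}}variable"):
        vname = var.get("name")
        variables[vname] = var.get("initial_value")
        units[vname] = var.get("units", "1")

    symbols: dict = {}
    odes = {}
    algebraic_raw = {}
    time_var = None
    for math in root.iter(f"{{{MATHML_NS}}}math"):
        for ap in math:
            if not isinstance(ap.tag, str) or _tag(ap) != "apply":
                continue
            eq = _mathml_to_sympy(ap, symbols)
            if not isinstance(eq, sp.Eq):
                raise CellMLError("top-level MathML must be equations")
            lhs, rhs = eq.lhs, eq.rhs
            if isinstance(lhs, sp.Derivative):
                state = str(lhs.args[0])
                time_var = str(lhs.args[1][0])
                odes[state] = rhs
            elif isinstance(lhs, sp.Symbol):
                algebraic_raw[str(lhs)] = rhs
            else:
                raise CellMLError(f"cannot interpret equation lhs {lhs}")

    if time_var is None:
        time_var = "t" if "t" in variables else "time"

    # resolve algebraic definitions into closed form (finite substitution)
    algebraic = dict(algebraic_raw)
    for _ in range(len(algebraic) + 1):
        changed = False
        for k, expr in algebraic.items():
            free = {str(s) for s in expr.free_symbols}
            hits = free & set(algebraic_raw)
            if hits - {k}:
                algebraic[k] = expr.subs(
                    {sp.Symbol(h): algebraic[h] for h in hits if h != k})
                changed = True
        if not changed:
            break
    else:
        raise CellMLError("cyclic algebraic definitions")
    for k in odes:
        odes[k] = odes[k].subs({sp.Symbol(a): e for a, e in algebraic.items()})

    state_names = list(odes)
    # canonical ordering: membrane potential first if present
    for vfirst in ("V", "Vm", "v"):
        if vfirst in state_names:
            state_names.remove(vfirst)
            state_names.insert(0, vfirst)
            break
    params = {}
    inits = {}
    for vname, init in variables.items():
        if vname in odes:
            if init is None:
                raise CellMLError(f"state {vname} lacks an initial value")
            inits[vname] = float(init)
        elif vname in algebraic_raw or vname == time_var:
            continue
        elif init is not None:
            params[vname] = float(init)
    if stimulus_var in params:
        params.pop(stimulus_var)

    unknown = set(current_map or {}) - set(algebraic_raw)
    if unknown:
        raise CellMLError(f"current map names undefined variables: "
                          f"{sorted(unknown)}")
    return CellMLModel(
        states=state_names, odes=odes, algebraic=algebraic, params=params,
        units=units, inits=inits, time_var=time_var,
        current_map=current_map, stimulus_var=stimulus_var,
        name=name or root.get("name", "cellml"))


# --------------------------------------------------------------------------
# export (toy model)
# --------------------------------------------------------------------------

def toy_symbolic_equations(model):
    """Symbolic mirror of the toy model equations for serialization.

    Returns ``(states, odes, algebraic, params, units)`` with the stimulus as
    the free symbol ``Istim``.
    """
    p = {k: sp.Float(v) for k, v in model.params.items()}
    V, f, n, Cai, Ki = sp.symbols("V f n Cai Ki")
    Istim = sp.Symbol("Istim")
    Ki_expr = Ki if model.ki_dynamics else sp.Symbol("Ki")
    E_K = sp.Float(26.71) * sp.log(sp.Symbol("Ko") / Ki_expr)
    Ko = sp.Symbol("Ko")
    d_inf = 1 / (1 + sp.exp(-(V + 10) / 6))
    f_inf = 1 / (1 + sp.exp((V + 25) / 6))
    n_inf = 1 / (1 + sp.exp(-(V - 5) / 9))
    k1_inf = 1 / (1 + sp.exp((V - E_K - 12) / 12))
    pump_reg = 1 / (1 + sp.exp((Ki_expr - p["Ki_half"]) / p["k_pump"]))
    I_Ca = p["G_Ca"] * d_inf * f * (V - p["E_Ca"])
    I_K = p["G_K"] * n * (V - E_K)
    I_K1 = p["G_K1"] * k1_inf * (V - E_K)
    I_NaK = p["G_NaK"] * (Ko / (Ko + sp.Float(1.5))) * pump_reg \
        / (1 + sp.exp(-(V + 80) / 25))
    I_Kp = p["G_Kp"] * (V - E_K) / (1 + sp.exp((sp.Float(7.488) - V)
                                               / sp.Float(5.98)))
    algebraic = {"E_K": E_K, "I_Ca": I_Ca, "I_K": I_K, "I_K1": I_K1,
                 "I_NaK": I_NaK, "I_Kp": I_Kp}
    odes = {
        "V": -(sp.Symbol("I_Ca") + sp.Symbol("I_K") + sp.Symbol("I_K1")
               + sp.Symbol("I_NaK") + sp.Symbol("I_Kp") + Istim),
        "f": (f_inf - f) / p["tau_f"],
        "n": (n_inf - n) / p["tau_n"],
        "Cai": -p["k_conv"] * sp.Symbol("I_Ca")
               - (Cai - p["Ca_rest"]) / p["tau_Ca"],
    }
    if model.ki_dynamics:
        odes["Ki"] = -p["kappa_K"] * (sp.Symbol("I_K") + sp.Symbol("I_K1")
                                      + sp.Symbol("I_Kp")
                                      - 2 * sp.Symbol("I_NaK") + Istim)
    init = model.initial_state
    states = dict(zip(model.state_names, init))
    units = dict(zip(model.state_names, model.state_units))
    # serialized parameters: only those appearing as free symbols
    params = {"Ko": model.params["Ko"]}
    if not model.ki_dynamics:
        params["Ki"] = model.params["Ki"]
    return states, odes, algebraic, params, units


TOY_CURRENT_MAP = {"I_K": "IKr", "I_K1": "IK1", "I_NaK": "INaK",
                   "I_Kp": "IKp", "I_Ca": "ICaL"}


def export_cellml(model, path) -> None:
    """Serialize a toy model instance to a CellML 2.0 subset file."""
    states, odes, algebraic, params, units = toy_symbolic_equations(model)
    root = etree.Element(f"{{{CELLML_NS}}}model",
                         nsmap={None: CELLML_NS, "m": MATHML_NS},
                         name="toy_ventricular")
    comp = etree.SubElement(root, f"{{{CELLML_NS}}}component", name="cell")
    etree.SubElement(comp, f"{{{CELLML_NS}}}variable", name="t", units="ms")
    for s, v in states.items():
        etree.SubElement(comp, f"{{{CELLML_NS}}}variable", name=s,
                         units=units.get(s, "1"), initial_value=repr(float(v)))
    for pname, v in params.items():
        etree.SubElement(comp, f"{{{CELLML_NS}}}variable", name=pname,
                         units="mM", initial_value=repr(float(v)))
    for aname in algebraic:
        etree.SubElement(comp, f"{{{CELLML_NS}}}variable", name=aname,
                         units="1")
    etree.SubElement(comp, f"{{{CELLML_NS}}}variable", name="Istim",
                     units="1", initial_value="0.0")
    math = etree.SubElement(comp, f"{{{MATHML_NS}}}math")
    tsym = sp.Symbol("t")

    def emit_eq(lhs_el, rhs_expr):
        ap = etree.SubElement(math, f"{{{MATHML_NS}}}apply")
        etree.SubElement(ap, f"{{{MATHML_NS}}}eq")
        ap.append(lhs_el)
        _sympy_to_mathml(rhs_expr, ap)

    for aname, expr in algebraic.items():
        ci = etree.Element(f"{{{MATHML_NS}}}ci")
        ci.text = aname
        emit_eq(ci, expr)
    for sname, expr in odes.items():
        dap = etree.Element(f"{{{MATHML_NS}}}apply")
        etree.SubElement(dap, f"{{{MATHML_NS}}}diff")
        bv = etree.SubElement(dap, f"{{{MATHML_NS}}}bvar")
        cit = etree.SubElement(bv, f"{{{MATHML_NS}}}ci")
        cit.text = "t"
        cis = etree.SubElement(dap, f"{{{MATHML_NS}}}ci")
        cis.text = sname
        emit_eq(dap, expr)
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="UTF-8")
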