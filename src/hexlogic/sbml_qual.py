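"""SBML Level 3 "qual" import/export for cellular logical models.

The Qualitative Models package of SBML Level 3 is the de-facto exchange
format for logical regulatory models; models drawn in any qual-capable editor
can be loaded here. The reader maps:

* each ``qualitativeSpecies`` to a :class:`~hexlogic.logic_core.Component`
  (``maxLevel`` attribute, defaulting to 1);
* each ``transition`` to the regulatory function of its output species —
  function terms become ``(resultLevel, expression)`` pairs, the
  ``defaultTerm`` (which must carry ``resultLevel="0"``) is the implicit
  else-branch;
* a species that no transition targets is an *input* component.

Only the MathML subset qual transitions actually use is understood: the
relational operators ``geq/gt/leq/lt/eq/neq`` over a ``ci``/``cn`` pair, the
logical connectives ``and/or/not``, and the constants ``true/false``. All
relations are normalised to the package's atom algebra (>=, ==, < on levels).
Anything else raises :class:`~hexlogic.errors.ParseError` naming the element.
"""

from __future__ import annotations

from lxml import etree

from .errors import ParseError, ValidationError
from .logic_core import (
    TRUE,
    FALSE,
    And,
    Atom,
    BoolConst,
    Component,
    Expr,
    LogicalFunction,
    LogicalModel,
    Not,
    Or,
)

__all__ = ["read_sbml_qual", "write_sbml_qual"]

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
QUAL_NS = "http://www.sbml.org/sbml/level3/version1/qual/version1"
MATH_NS = "http://www.w3.org/1998/Math/MathML"

_NSMAP = {None: SBML_NS, "qual": QUAL_NS}


def _q(tag: str) -> str:
    return f"{{{QUAL_NS}}}{tag}"


def _s(tag: str) -> str:
    return f"{{{SBML_NS}}}{tag}"


def _m(tag: str) -> str:
    return f"{{{MATH_NS}}}{tag}"


def _local(el) -> str:
    return etree.QName(el).localname


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _parse_operand_pair(apply_el) -> tuple[str, int, bool]:
    """Return (component, constant, ci_first) for a relational apply node."""
    operands = list(apply_el)[1:]
    if len(operands) != 2:
        raise ParseError(
            f"relational operator needs two operands, got {len(operands)} "
            f"(element {_local(apply_el)})"
        )
    kinds = [_local(o) for o in operands]
    if kinds == ["ci", "cn"]:
        ci, cn = operands
        ci_first = True
    elif kinds == ["cn", "ci"]:
        cn, ci = operands
        ci_first = False
    else:
        raise ParseError(
            f"relational operands must be one ci and one cn, got {kinds}"
        )
    try:
        value = int(float(cn.text.strip()))
    except (TypeError, ValueError):
        raise ParseError(f"non-integer cn value {cn.text!r}") from None
    return ci.text.strip(), value, ci_first


def _math_to_expr(el) -> Expr:
    name = _local(el)
    if name == "math":
        children = list(el)
        if len(children) != 1:
            raise ParseError("math element must have exactly one child")
        return _math_to_expr(children[0])
    if name == "true":
        return TRUE
    if name == "false":
        return FALSE
    if name != "apply":
        raise ParseError(f"unsupported MathML element <{name}>")
    children = list(el)
    if not children:
        raise ParseError("empty apply element")
    op = _local(children[0])
    if op in ("and", "or"):
        sub = [_math_to_expr(c) for c in children[1:]]
        if not sub:
            raise ParseError(f"<{op}> with no operands")
        return And(*sub) if op == "and" else Or(*sub)
    if op == "not":
        if len(children) != 2:
            raise ParseError("<not> needs exactly one operand")
        return Not(_math_to_expr(children[1]))
    if op in ("geq", "gt", "leq", "lt", "eq", "neq"):
        comp, v, ci_first = _parse_operand_pair(el)
        if not ci_first:
            # mirror the relation so the component is on the left
            op = {"geq": "leq", "leq": "geq", "gt": "lt", "lt": "gt"}.get(op, op)
        if op == "geq":
            return Atom(comp, ">=", v)
        if op == "gt":
            return Atom(comp, ">=", v + 1)
        if op == "lt":
            return Atom(comp, "<", v)
        if op == "leq":
            return Atom(comp, "<", v + 1)
        if op == "eq":
            return Atom(comp, "==", v)
        return Not(Atom(comp, "==", v))  # neq
    raise ParseError(f"unsupported MathML operator <{op}>")


def read_sbml_qual(source) -> LogicalModel:
    """Read a logical model from SBML L3 + qual.

    ``source`` is a path, a file object, or the document text itself.
    """
    if isinstance(source, (str, bytes)) and (
        (isinstance(source, str) and source.lstrip().startswith("<"))
        or (isinstance(source, bytes) and source.lstrip().startswith(b"<"))
    ):
        if isinstance(source, str):
            source = source.encode()
        try:
            root = etree.fromstring(source)
        except etree.XMLSyntaxError as e:
            raise ParseError(f"not well-formed XML: {e}") from None
    else:
        try:
            root = etree.parse(str(source)).getroot()
        except (etree.XMLSyntaxError, OSError) as e:
            raise ParseError(f"cannot read SBML document: {e}") from None

    model_el = root.find(_s("model"))
    if model_el is None:
        raise ParseError("document has no <model> element")
    species_list = model_el.find(_q("listOfQualitativeSpecies"))
    if species_list is None:
        raise ParseError("model has no qual:listOfQualitativeSpecies")

    order: list[str] = []
    max_levels: dict[str, int] = {}
    for sp in species_list.findall(_q("qualitativeSpecies")):
        sid = sp.get(_q("id"))
        if not sid:
            raise ParseError("qualitativeSpecies without qual:id")
        if sid in max_levels:
            raise ParseError(f"duplicate qualitativeSpecies id {sid!r}")
        raw = sp.get(_q("maxLevel"))
        max_levels[sid] = int(raw) if raw is not None else 1
        order.append(sid)

    functions: dict[str, LogicalFunction] = {}
    transitions_list = model_el.find(_q("listOfTransitions"))
    transitions = (
        transitions_list.findall(_q("transition"))
        if transitions_list is not None
        else []
    )
    for tr in transitions:
        tid = tr.get(_q("id"), "?")
        out_list = tr.find(_q("listOfOutputs"))
        outputs = out_list.findall(_q("output")) if out_list is not None else []
        if not outputs:
            raise ParseError(f"transition {tid!r} has no outputs")
        terms: list[tuple[int, Expr]] = []
        default_seen = False
        ft_list = tr.find(_q("listOfFunctionTerms"))
        if ft_list is None:
            raise ParseError(f"transition {tid!r} has no listOfFunctionTerms")
        for term in ft_list:
            lname = _local(term)
            lv = term.get(_q("resultLevel"))
            if lv is None:
                raise ParseError(f"transition {tid!r}: term without resultLevel")
            lv = int(lv)
            if lname == "defaultTerm":
                if lv != 0:
                    raise ParseError(
                        f"transition {tid!r}: defaultTerm resultLevel must be 0, "
                        f"got {lv}"
                    )
                default_seen = True
            elif lname == "functionTerm":
                if lv == 0:
                    raise ParseError(
                        f"transition {tid!r}: functionTerm with resultLevel 0 is "
                        "not supported (use the defaultTerm)"
                    )
                math = term.find(_m("math"))
                if math is None:
                    raise ParseError(f"transition {tid!r}: functionTerm without math")
                terms.append((lv, _math_to_expr(math)))
            else:
                raise ParseError(f"transition {tid!r}: unexpected element <{lname}>")
        if not default_seen:
            raise ParseError(f"transition {tid!r} has no defaultTerm")
        for out in outputs:
            target = out.get(_q("qualitativeSpecies"))
            if target not in max_levels:
                raise ParseError(
                    f"transition {tid!r} targets undeclared species {target!r}"
                )
            if target in functions:
                raise ParseError(
                    f"species {target!r} is the output of more than one transition"
                )
            functions[target] = LogicalFunction(target, terms)

    components = [
        Component(name, max_level=max_levels[name], is_input=name not in functions)
        for name in order
    ]
    try:
        return LogicalModel(components, functions)
    except ValidationError as e:
        raise ParseError(f"invalid qual model: {e}") from None


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def _expr_to_math(expr: Expr, parent) -> None:
    if isinstance(expr, BoolConst):
        etree.SubElement(parent, _m("true" if expr.value else "false"))
        return
    if isinstance(expr, Atom):
        apply_el = etree.SubElement(parent, _m("apply"))
        if expr.op == ">=":
            opname = "geq"
        elif expr.op == "==":
            opname = "eq"
        else:
            opname = "lt"
        etree.SubElement(apply_el, _m(opname))
        ci = etree.SubElement(apply_el, _m("ci"))
        ci.text = f" {expr.component} "
        cn = etree.SubElement(apply_el, _m("cn"))
        cn.set("type", "integer")
        cn.text = f" {expr.level} "
        return
    if isinstance(expr, Not):
        apply_el = etree.SubElement(parent, _m("apply"))
        etree.SubElement(apply_el, _m("not"))
        _expr_to_math(expr.child, apply_el)
        return
    if isinstance(expr, (And, Or)):
        if not expr.children:
            etree.SubElement(
                parent, _m("true" if isinstance(expr, And) else "false")
            )
            return
        if len(expr.children) == 1:
            _expr_to_math(expr.children[0], parent)
            return
        apply_el = etree.SubElement(parent, _m("apply"))
        etree.SubElement(apply_el, _m("and" if isinstance(expr, And) else "or"))
        for c in expr.children:
            _expr_to_math(c, apply_el)
        return
    raise ValidationError(f"cannot serialise expression node {type(expr).__name__}")


def write_sbml_qual(model: LogicalModel, path=None, model_id: str = "model") -> str:
    """Serialise a model to SBML L3 + qual. Returns the document text.

    When ``path`` is given the document is also written there.
    """
    root = etree.Element(_s("sbml"), nsmap=_NSMAP)
    root.set("level", "3")
    root.set("version", "1")
    root.set(f"{{{QUAL_NS}}}required", "true")
    model_el = etree.SubElement(root, _s("model"))
    model_el.set("id", model_id)

    comp_list = etree.SubElement(model_el, _s("listOfCompartments"))
    comp = etree.SubElement(comp_list, _s("compartment"))
    comp.set("id", "default")
    comp.set("constant", "true")

    sp_list = etree.SubElement(model_el, _q("listOfQualitativeSpecies"))
    for c in model.components:
        sp = etree.SubElement(sp_list, _q("qualitativeSpecies"))
        sp.set(_q("id"), c.name)
        sp.set(_q("compartment"), "default")
        sp.set(_q("constant"), "true" if c.is_input else "false")
        sp.set(_q("maxLevel"), str(c.max_level))

    if model.internals:
        tr_list = etree.SubElement(model_el, _q("listOfTransitions"))
        for c in model.internals:
            fn = model.functions[c.name]
            tr = etree.SubElement(tr_list, _q("transition"))
            tr.set(_q("id"), f"tr_{c.name}")
            regulators = sorted({a.component for _, ex in fn.terms for a in ex.atoms()})
            if regulators:
                in_list = etree.SubElement(tr, _q("listOfInputs"))
                for i, reg in enumerate(regulators):
                    inp = etree.SubElement(in_list, _q("input"))
                    inp.set(_q("id"), f"tr_{c.name}_in_{i}")
                    inp.set(_q("qualitativeSpecies"), reg)
                    inp.set(_q("transitionEffect"), "none")
            out_list = etree.SubElement(tr, _q("listOfOutputs"))
            out = etree.SubElement(out_list, _q("output"))
            out.set(_q("id"), f"tr_{c.name}_out")
            out.set(_q("qualitativeSpecies"), c.name)
            out.set(_q("transitionEffect"), "assignmentLevel")
            ft_list = etree.SubElement(tr, _q("listOfFunctionTerms"))
            for lv, ex in fn.terms:
                ft = etree.SubElement(ft_list, _q("functionTerm"))
                ft.set(_q("resultLevel"), str(lv))
                math = etree.SubElement(ft, _m("math"))
                _expr_to_math(ex, math)
            dt = etree.SubElement(ft_list, _q("defaultTerm"))
            dt.set(_q("resultLevel"), "0")

    text = etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode()
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
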