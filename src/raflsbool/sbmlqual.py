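"""Reading the Boolean subset of SBML-qual (SBML Level 3, qual package).

Only strictly Boolean models are accepted: every qualitative species must
have ``maxLevel`` <= 1 and every transition's function terms may use only
MathML ``and``/``or``/``not`` plus ``eq`` comparisons of a species against
0/1 (a bare ``ci`` is read as "species is 1"). Anything outside the dialect
raises :class:`UnsupportedModelError` naming the offending element; nothing
is silently dropped.
"""

from __future__ import annotations

from typing import Dict

from lxml import etree

from .bnet import PHENOTYPE_SUFFIX
from .errors import UnsupportedModelError
from .expressions import Const, Not, RuleExpression, Var, make_or, simplify
from .network import BooleanNetwork, sanitize_name

__all__ = ["parse_sbml_qual"]

QUAL_NS = "http://www.sbml.org/sbml/level3/version1/qual/version1"
MATH_NS = "http://www.w3.org/1998/Math/MathML"


def _q(attr: str) -> str:
    return f"{{{QUAL_NS}}}{attr}"


def _local(el) -> str:
    return etree.QName(el).localname


def _parse_math(el, id_to_name: Dict[str, str], transition_id: str) -> RuleExpression:
    """MathML -> RuleExpression for the restricted Boolean dialect."""

    def err(msg: str):
        return UnsupportedModelError(f"transition {transition_id!r}: {msg}")

    def parse(node) -> RuleExpression:
        tag = _local(node)
        if tag == "math":
            kids = [c for c in node if isinstance(c.tag, str)]
            if len(kids) != 1:
                raise err("math element must contain exactly one expression")
            return parse(kids[0])
        if tag == "ci":
            sid = (node.text or "").strip()
            if sid not in id_to_name:
                raise err(f"unknown species {sid!r} in math")
            return Var(id_to_name[sid])
        if tag == "true":
            return Const(True)
        if tag == "false":
            return Const(False)
        if tag == "apply":
            kids = [c for c in node if isinstance(c.tag, str)]
            if not kids:
                raise err("empty apply")
            op = _local(kids[0])
            args = kids[1:]
            if op == "not":
                if len(args) != 1:
                    raise err("not takes one argument")
                return Not(parse(args[0]))
            if op in ("and", "or"):
                parsed = [parse(a) for a in args]
                if not parsed:
                    raise err(f"{op} with no arguments")
                if len(parsed) == 1:
                    return parsed[0]
                from .expressions import make_and

                return make_and(parsed) if op == "and" else make_or(parsed)
            if op == "eq":
                if len(args) != 2:
                    raise err("eq takes two arguments")
                tags = [_local(a) for a in args]
                if tags == ["ci", "cn"]:
                    ci, cn = args
                elif tags == ["cn", "ci"]:
                    cn, ci = args
                else:
                    raise err("eq must compare a species against a constant")
                try:
                    level = int(float((cn.text or "").strip()))
                except ValueError:
                    raise err(f"non-numeric constant {cn.text!r}") from None
                if level not in (0, 1):
                    raise err(f"comparison against level {level} (Boolean models only)")
                var = parse(ci)
                return var if level == 1 else Not(var)
            raise err(f"unsupported MathML operator {op!r}")
        raise err(f"unsupported MathML element {tag!r}")

    return parse(el)


def parse_sbml_qual(document: str | bytes) -> BooleanNetwork:
    """Parse an SBML-qual document (text or bytes) into a Boolean network.

    One node per qualitative species (names sanitised to ``[A-Za-z0-9_]+``);
    species that are not the output of any transition become self-rule
    inputs. Nodes named ``*_phenotype`` are flagged as phenotypes.
    """
    if isinstance(document, str):
        document = document.encode()
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise UnsupportedModelError(f"not well-formed XML: {exc}") from None

    species = root.findall(f".//{{{QUAL_NS}}}qualitativeSpecies")
    if not species:
        raise UnsupportedModelError("document contains no qualitative species")

    id_to_name: Dict[str, str] = {}
    nodes = []
    for sp in species:
        sid = sp.get(_q("id")) or sp.get("id")
        if sid is None:
            raise UnsupportedModelError("qualitativeSpecies without an id")
        max_level = sp.get(_q("maxLevel")) or sp.get("maxLevel")
        if max_level is not None and int(max_level) > 1:
            raise UnsupportedModelError(
                f"species {sid!r} has maxLevel={max_level}; only Boolean models supported"
            )
        name = sanitize_name(sp.get(_q("name")) or sp.get("name") or sid)
        if name in id_to_name.values():
            raise UnsupportedModelError(f"sanitised name collision on {name!r}")
        id_to_name[sid] = name
        nodes.append(name)

    rules: Dict[str, RuleExpression] = {}
    for tr in root.findall(f".//{{{QUAL_NS}}}transition"):
        tid = tr.get(_q("id")) or tr.get("id") or "<anonymous>"
        outputs = tr.findall(f"{{{QUAL_NS}}}listOfOutputs/{{{QUAL_NS}}}output")
        terms_parent = tr.find(f"{{{QUAL_NS}}}listOfFunctionTerms")
        if terms_parent is None:
            raise UnsupportedModelError(f"transition {tid!r} has no function terms")

        default_el = terms_parent.find(f"{{{QUAL_NS}}}defaultTerm")
        if default_el is None:
            raise UnsupportedModelError(f"transition {tid!r} has no defaultTerm")
        default = int(default_el.get(_q("resultLevel")) or default_el.get("resultLevel"))
        if default not in (0, 1):
            raise UnsupportedModelError(f"transition {tid!r}: defaultTerm level {default}")

        level_terms = {0: [], 1: []}
        for ft in terms_parent.findall(f"{{{QUAL_NS}}}functionTerm"):
            level = int(ft.get(_q("resultLevel")) or ft.get("resultLevel"))
            if level not in (0, 1):
                raise UnsupportedModelError(f"transition {tid!r}: resultLevel {level}")
            math = ft.find(f"{{{MATH_NS}}}math")
            if math is None:
                raise UnsupportedModelError(f"transition {tid!r}: functionTerm without math")
            level_terms[level].append(_parse_math(math, id_to_name, tid))

        # value is 1 when a level-1 term fires, or by default when no
        # level-0 term fires (function terms are assumed non-overlapping)
        on = make_or(level_terms[1]) if level_terms[1] else Const(False)
        if default == 1:
            off = make_or(level_terms[0]) if level_terms[0] else Const(False)
            rule = simplify(make_or([on, Not(off)]))
        else:
            rule = simplify(on)

        for out in outputs:
            sid = out.get(_q("qualitativeSpecies")) or out.get("qualitativeSpecies")
            if sid not in id_to_name:
                raise UnsupportedModelError(f"transition {tid!r}: unknown output {sid!r}")
            name = id_to_name[sid]
            if name in rules:
                raise UnsupportedModelError(
                    f"species {name!r} is the output of more than one transition"
                )
            rules[name] = rule

    for name in nodes:
        rules.setdefault(name, Var(name))  # untargeted species are inputs

    phenotypes = tuple(n for n in nodes if n.endswith(PHENOTYPE_SUFFIX))
    return BooleanNetwork(nodes, rules, phenotypes)
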