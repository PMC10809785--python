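"""Independent brute-force oracle for three-valued predicate evaluation.

The oracle never calls the engine's recursive Kleene evaluator: it computes
each leaf's truth value directly with plain Python comparisons, then
enumerates every TRUE/FALSE substitution of the unknown leaves and evaluates
the tree as a plain boolean formula.  The three-valued verdict is TRUE iff
all substitutions are true, FALSE iff all are false, UNKNOWN otherwise.
"""

from itertools import product

from survplan.engine import FactSet, K3, UNKNOWN
from survplan.rulebase import And, Leaf, Not, Or, iter_leaves


def _leaf_truth(atom, facts: FactSet):
    """True/False/None(=unknown) for one atom, via plain comparisons."""
    value = facts.resolve(atom)
    if value is UNKNOWN:
        return None
    if atom.op == "==":
        return value == atom.value
    if atom.op == "!=":
        return value != atom.value
    if atom.op == ">=":
        return value >= atom.value
    if atom.op == "<=":
        return value <= atom.value
    if atom.op == "in":
        return value in atom.value
    raise ValueError(atom.op)


def _eval_bool(node, values, counter):
    if isinstance(node, Leaf):
        i = counter[0]
        counter[0] += 1
        return values[i]
    if isinstance(node, And):
        out = True
        for child in node.children:
            out = _eval_bool(child, values, counter) and out
        return out
    if isinstance(node, Or):
        out = False
        for child in node.children:
            out = _eval_bool(child, values, counter) or out
        return out
    if isinstance(node, Not):
        return not _eval_bool(node.child, values, counter)
    raise TypeError(node)


def brute_force_eval(predicate, facts: FactSet) -> K3:
    truths = [_leaf_truth(atom, facts) for atom in iter_leaves(predicate)]
    unknown_positions = [i for i, t in enumerate(truths) if t is None]
    results = set()
    for bits in product([False, True], repeat=len(unknown_positions)):
        values = list(truths)
        for pos, bit in zip(unknown_positions, bits):
            values[pos] = bit
        results.add(_eval_bool(predicate, values, [0]))
    if results == {True}:
        return K3.TRUE
    if results == {False}:
        return K3.FALSE
    return K3.UNKNOWN


# palettes of concrete fact values per fact type; includes UNKNOWN so every
# three-valued branch is exercised
_PALETTES = {
    "numeric": (UNKNOWN, 0.5, 500.0),
    "bool": (UNKNOWN, True, False),
    "sex": (UNKNOWN, "male", "female"),
    "organ_status": (UNKNOWN, "intact", "partially_removed"),
}


def fact_assignments(predicate):
    """All assignments of palette values to the predicate's distinct fact
    keys (3^k FactSets for k distinct keys)."""
    from survplan.rulebase import FACT_VOCABULARY

    atoms = {}
    for atom in iter_leaves(predicate):
        atoms[atom.key] = atom
    keys = list(atoms)
    palettes = [_PALETTES[FACT_VOCABULARY[atoms[k].fact][0]] for k in keys]
    for combo in product(*palettes):
        facts = FactSet()
        for key, value in zip(keys, combo):
            atom = atoms[key]
            facts.set(atom.fact, atom.arg, value, "recorded")
        yield facts
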