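"""Species history: the rooted, dated tree the simulator evolves sequences on.

The default history is an amphidiploid design: two diploid progenitor
lineages (an A-genome and a D-genome diploid), five allotetraploid species
each contributing one tip per subgenome (``<species>_A`` inside the A clade,
``<species>_D`` inside the D clade), and a distant outgroup.  Branch lengths
are stored in years; expected substitutions/site on a branch are
``clock_rate * multiplier * years``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterator

__all__ = [
    "TreeNode",
    "SpeciesHistory",
    "make_history",
    "DEFAULT_SPLIT_TIMES",
    "DEFAULT_CLOCK_RATE",
    "POLYPLOIDS",
    "A_DIPLOID",
    "D_DIPLOID",
    "OUTGROUP",
]

#: per-site per-year synonymous substitution rate used throughout
DEFAULT_CLOCK_RATE = 3.48e-9

POLYPLOIDS = ("Gh", "Gb", "Gt", "Gd", "Gm")
A_DIPLOID = "Ga"
D_DIPLOID = "Gr"
OUTGROUP = "outgroup"

#: node ages in years before present (keys are internal-node names)
DEFAULT_SPLIT_TIMES = {
    "root": 58.5e6,        # outgroup vs cotton clade
    "ingroup": 5.0e6,      # A-genome vs D-genome diploid lineages
    "cladeA": 1.3e6,       # A diploid vs polyploid A subgenomes
    "cladeD": 1.3e6,       # D diploid vs polyploid D subgenomes
    # within-polyploid topology: (Gm, ((Gh, Gt), (Gb, Gd)))
    "polyA": 0.63e6,       # Gm split from the other four
    "polyD": 0.63e6,
    "ghgt_gbgd_A": 0.45e6,
    "ghgt_gbgd_D": 0.45e6,
    "ghgt_A": 0.30e6,
    "ghgt_D": 0.30e6,
    "gbgd_A": 0.20e6,
    "gbgd_D": 0.20e6,
}


@dataclass
class TreeNode:
    name: str
    age: float = 0.0  # years before present; 0 at tips
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def branch_years(self) -> float:
        if self.parent is None:
            return 0.0
        return self.parent.age - self.age

    def walk(self) -> Iterator["TreeNode"]:
        """Deterministic preorder traversal."""
        yield self
        for child in self.children:
            yield from child.walk()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.walk() if n.is_leaf]

    def find(self, name: str) -> "TreeNode":
        for n in self.walk():
            if n.name == name:
                return n
        raise KeyError(name)


class SpeciesHistory:
    """A validated dated tree plus clock rate and per-branch rate multipliers.

    Parameters
    ----------
    root:
        Root of the dated tree; ``age`` decreases root -> tip, tips at 0.
    clock_rate:
        Substitutions per site per year on a multiplier-1 branch.
    rate_multipliers:
        Map from node name to a dimensionless factor (>= 0) applied to the
        branch above that node.  Missing branches default to 1.
    """

    def __init__(
        self,
        root: TreeNode,
        clock_rate: float = DEFAULT_CLOCK_RATE,
        rate_multipliers: dict[str, float] | None = None,
    ) -> None:
        if clock_rate <= 0:
            raise ValueError(f"clock_rate must be > 0, got {clock_rate}")
        self.root = root
        self.clock_rate = float(clock_rate)
        self.rate_multipliers = dict(rate_multipliers or {})
        self._validate()

    def _validate(self) -> None:
        for node in self.root.walk():
            if node.age < 0:
                raise ValueError(f"negative age at node {node.name!r}")
            for child in node.children:
                child.parent = node
                if child.age > node.age:
                    raise ValueError(
                        f"node {child.name!r} (age {child.age}) is older than "
                        f"its parent {node.name!r} (age {node.age})"
                    )
        names = [n.name for n in self.root.walk()]
        if len(set(names)) != len(names):
            raise ValueError("node names must be unique")
        for name, m in self.rate_multipliers.items():
            if not (m >= 0 and m == m and m != float("inf")):
                raise ValueError(f"multiplier for {name!r} must be finite and >= 0")

    # -- queries ----------------------------------------------------------

    @property
    def tip_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    def multiplier(self, name: str) -> float:
        return self.rate_multipliers.get(name, 1.0)

    def branch_subs_per_site(self, node: TreeNode) -> float:
        """Expected substitutions/site on the branch above *node*."""
        return self.clock_rate * self.multiplier(node.name) * node.branch_years

    def split_age(self, tip1: str, tip2: str) -> float:
        """Age (years) of the most recent common ancestor of two tips."""
        a = self.root.find(tip1)
        b = self.root.find(tip2)
        ancestors = set()
        n: TreeNode | None = a
        while n is not None:
            ancestors.add(id(n))
            n = n.parent
        n = b
        while n is not None:
            if id(n) in ancestors:
                return n.age
            n = n.parent
        raise ValueError("tips do not share an ancestor")

    def expected_pairwise_divergence(self, tip1: str, tip2: str) -> float:
        """Expected substitutions/site separating two tips (path sum)."""
        age = self.split_age(tip1, tip2)
        total = 0.0
        for tip in (tip1, tip2):
            n = self.root.find(tip)
            while n.parent is not None and n.age < age:
                years = min(n.parent.age, age) - n.age
                total += self.clock_rate * self.multiplier(n.name) * years
                n = n.parent
        return total

    def prune_to(self, tips: list[str]) -> "SpeciesHistory":
        """History restricted to *tips* (unary internal nodes collapsed).

        Collapsed multipliers are time-averaged so expected substitutions per
        branch are preserved exactly.
        """
        keep = set(tips)
        missing = keep - set(self.tip_names)
        if missing:
            raise KeyError(f"unknown tips: {sorted(missing)}")

        def rebuild(node: TreeNode) -> TreeNode | None:
            if node.is_leaf:
                return TreeNode(node.name, node.age) if node.name in keep else None
            kept = [c for c in (rebuild(c) for c in node.children) if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                return kept[0]
            new = TreeNode(node.name, node.age)
            new.children = kept
            for c in kept:
                c.parent = new
            return new

        new_root = rebuild(self.root)
        if new_root is None or new_root.is_leaf:
            raise ValueError("pruning needs at least two retained tips")
        mult: dict[str, float] = {}
        for node in new_root.walk():
            if node.parent is None:
                continue
            # accumulate expected subs along the original path, then average
            orig = self.root.find(node.name)
            top_age = node.parent.age
            subs = 0.0
            n = orig
            while n.parent is not None and n.age < top_age:
                years = min(n.parent.age, top_age) - n.age
                subs += self.multiplier(n.name) * years
                n = n.parent
            years_total = top_age - node.age
            if years_total > 0:
                mult[node.name] = subs / years_total
        return SpeciesHistory(new_root, self.clock_rate, mult)

    # -- serialization ----------------------------------------------------

    def to_newick(self) -> str:
        """Newick with branch lengths in years; clock rate in a comment."""

        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                body = node.name
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")" + node.name
            if node.parent is None:
                return body
            return f"{body}:{node.branch_years:.10g}"

        return f"[&clock_rate={self.clock_rate:.10g}]{fmt(self.root)};"

    @classmethod
    def from_newick(
        cls, text: str, rate_multipliers: dict[str, float] | None = None
    ) -> "SpeciesHistory":
        text = text.strip()
        clock_rate = DEFAULT_CLOCK_RATE
        m = re.match(r"\[&clock_rate=([^\]]+)\]", text)
        if m:
            clock_rate = float(m.group(1))
            text = text[m.end() :]
        if not text.endswith(";"):
            raise ValueError("newick string must end with ';'")
        tokens = re.findall(r"[(),;]|[^(),;:]+(?::[0-9eE.+-]+)?", text[:-1])

        def parse_label(tok: str) -> tuple[str, float]:
            if ":" in tok:
                name, bl = tok.rsplit(":", 1)
                return name, float(bl)
            return tok, 0.0

        stack: list[list[tuple[TreeNode, float]]] = []
        current: list[tuple[TreeNode, float]] = []
        root_entry: tuple[TreeNode, float] | None = None
        for tok in tokens:
            if tok == "(":
                stack.append(current)
                current = []
            elif tok == ",":
                continue
            elif tok == ")":
                children = current
                current = stack.pop()
                node = TreeNode("", 0.0)
                node.children = [c for c, _ in children]
                node._child_bls = [bl for _, bl in children]  # type: ignore[attr-defined]
                current.append((node, 0.0))
            else:
                name, bl = parse_label(tok)
                if current and not current[-1][0].is_leaf and current[-1][0].name == "":
                    node, _ = current.pop()
                    node.name = name
                    current.append((node, bl))
                else:
                    current.append((TreeNode(name, 0.0), bl))
        if len(current) != 1:
            raise ValueError("malformed newick")
        root_entry = current[0]
        root = root_entry[0]

        # convert branch lengths (years) into ages bottom-up
        def set_ages(node: TreeNode) -> float:
            if node.is_leaf:
                node.age = 0.0
                return 0.0
            bls = getattr(node, "_child_bls", [0.0] * len(node.children))
            ages = []
            for child, bl in zip(node.children, bls):
                set_ages(child)
                ages.append(child.age + bl)
            node.age = max(ages)
            return node.age

        # recover per-child branch lengths recorded during parsing
        def attach_bls(node: TreeNode) -> None:
            if node.is_leaf:
                return
            for child in node.children:
                child.parent = node
                attach_bls(child)

        # Branch lengths live on tokens; rebuild ages via recorded _child_bls
        def assign(node: TreeNode) -> None:
            bls = getattr(node, "_child_bls", None)
            if bls is None:
                return
            for child, bl in zip(node.children, bls):
                child.age = node.age - bl
                assign(child)

        set_ages(root)
        assign(root)
        attach_bls(root)
        return cls(root, clock_rate, rate_multipliers)


def _default_topology(split_times: dict[str, float]) -> TreeNode:
    t = split_times

    def tip(name: str) -> TreeNode:
        return TreeNode(name, 0.0)

    def node(name: str, *children: TreeNode) -> TreeNode:
        n = TreeNode(name, t[name])
        n.children = list(children)
        return n

    def poly_clade(sub: str) -> TreeNode:
        s = sub  # "A" or "D"
        return node(
            f"poly{s}",
            tip(f"Gm_{s}"),
            node(
                f"ghgt_gbgd_{s}",
                node(f"ghgt_{s}", tip(f"Gh_{s}"), tip(f"Gt_{s}")),
                node(f"gbgd_{s}", tip(f"Gb_{s}"), tip(f"Gd_{s}")),
            ),
        )

    return node(
        "root",
        tip(OUTGROUP),
        node(
            "ingroup",
            node("cladeA", tip(A_DIPLOID), poly_clade("A")),
            node("cladeD", tip(D_DIPLOID), poly_clade("D")),
        ),
    )


def make_history(
    split_times: dict[str, float] | None = None,
    clock_rate: float = DEFAULT_CLOCK_RATE,
    rate_multipliers: dict[str, float] | None = None,
    topology: Callable[[dict[str, float]], TreeNode] = _default_topology,
) -> SpeciesHistory:
    """Build a validated :class:`SpeciesHistory`.

    *split_times* overrides entries of :data:`DEFAULT_SPLIT_TIMES`; unknown
    keys are rejected.  Raises ``ValueError`` for negative times or
    non-ultrametric assignments (a node older than its parent).
    """
    times = dict(DEFAULT_SPLIT_TIMES)
    if split_times:
        unknown = set(split_times) - set(times)
        if unknown:
            raise KeyError(f"unknown split-time keys: {sorted(unknown)}")
        times.update(split_times)
    for name, t in times.items():
        if t < 0:
            raise ValueError(f"negative split time for {name!r}: {t}")
    root = topology(times)
    return SpeciesHistory(root, clock_rate, rate_multipliers)
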