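"""Shared builders used by multiple test modules (kept importable as a
plain module: the tests directory is not a package)."""

from polyrate.synthetic_data.history import SpeciesHistory, TreeNode


def pair_history(split_years: float, clock_rate: float = 3.48e-9) -> SpeciesHistory:
    """Minimal two-tip dated tree for round-trip dating experiments."""
    root = TreeNode("root", split_years)
    a, b = TreeNode("a", 0.0), TreeNode("b", 0.0)
    root.children = [a, b]
    return SpeciesHistory(root, clock_rate)


def triplet_history(
    tip_split: float = 0.3e6,
    out_split: float = 1.3e6,
    clock_rate: float = 3.48e-9,
    tip1_multiplier: float = 1.0,
) -> SpeciesHistory:
    """(outgroup, (t1, t2)) dated tree with an optional rate multiplier on
    the t1 pendant branch."""
    t1, t2, out = TreeNode("t1", 0.0), TreeNode("t2", 0.0), TreeNode("out", 0.0)
    inner = TreeNode("inner", tip_split)
    inner.children = [t1, t2]
    root = TreeNode("root", out_split)
    root.children = [out, inner]
    return SpeciesHistory(root, clock_rate, {"t1": tip1_multiplier})
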