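#!/usr/bin/env python
"""Build the three idealized stenosed-artery models and write them as
vessel-tree JSON.

The benchmark geometry is a 75 mm straight vessel of 3 mm diameter with a
10 mm stenosis at mid-vessel narrowing the lumen area to 20 % of healthy.
Model 1 has no side branch; models 2 and 3 add a 2.5 mm branch 25 mm
upstream or downstream of the stenosis centre.  Outlet resistances come
from the hyperemic structured-tree model of each outlet diameter.
"""

from pathlib import Path

from ffr0d import IdealizedFixtureSpec, StructuredTreeParams, make_idealized, tree_resistance
from ffr0d.synthetic_data import VARIANTS, write_tree

OUT = Path(__file__).resolve().parent.parent / "results" / "trees"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = StructuredTreeParams()
    print("hyperemic structured-tree outlet resistances (Pa s/m^3):")
    print(f"  main outlet (3.0 mm): {tree_resistance(3e-3, params):.4e}")
    print(f"  side branch (2.5 mm): {tree_resistance(2.5e-3, params):.4e}")
    for variant in VARIANTS:
        tree = make_idealized(IdealizedFixtureSpec(variant=variant))
        path = OUT / f"{variant}.json"
        write_tree(tree, path)
        print(f"wrote {path} ({len(tree.side_branches)} side branch(es))")


if __name__ == "__main__":
    main()
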