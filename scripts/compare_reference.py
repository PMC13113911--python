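#!/usr/bin/env python
"""Best-effort comparison of recomputed descriptors with the packaged
reference matrix.

The reference values for the nine membrane proteins (1C3W, 1F88, 1J4N,
2RH1, 3ODU, 4DKL, 2A79, 1C17, 1OTS) depend on conventions that cannot be
fully reconstructed (see docs/methods.md); this script computes the
six-descriptor vector for locally available structure files and prints
them side by side with the reference rows.  It performs no downloads:
pass paths to PDB/mmCIF files you have fetched yourself, named so the
stem matches the reference id (e.g. 1c3w.pdb).

Usage:  python scripts/compare_reference.py 1c3w.pdb 1ots.cif ...
"""

import argparse
from pathlib import Path

from chirobiophore import assemble_vector, load_reference_matrix
from chirobiophore.chirality_space import DESCRIPTOR_NAMES


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("structures", nargs="+", type=Path,
                    help="Local PDB/mmCIF files (stem = reference id).")
    args = ap.parse_args()

    reference = load_reference_matrix().frame
    header = f"{'id':>6s} {'source':>10s} " + \
        " ".join(f"{n:>9s}" for n in DESCRIPTOR_NAMES)
    print(header)
    for path in args.structures:
        pid = path.stem.upper()
        vec = assemble_vector(path, structure_id=pid)
        row = " ".join(f"{v:9.3f}" for v in vec.as_array())
        print(f"{pid:>6s} {'computed':>10s} {row}")
        if pid in reference.index:
            ref = " ".join(f"{v:9.3f}" for v in reference.loc[pid])
            print(f"{pid:>6s} {'reference':>10s} {ref}")
        else:
            print(f"{pid:>6s} {'reference':>10s} (not in reference set)")


if __name__ == "__main__":
    main()
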