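"""Regenerate the packaged synthetic reference genome and coding table.

The packaged reference (``src/mitorho/data/rcrs_synthetic.fasta``) is a
deterministic synthetic stand-in for the 16,569-bp revised Cambridge
Reference Sequence: it has human-mtDNA base composition, the real rCRS
gene coordinates, and the small set of control-region / coding positions
referenced by the packaged U5-style motif rules pinned to their real rCRS
bases, so that classic variant labels such as ``16114A`` (a C->A
transversion) or ``16311`` (a T->C transition) are well-formed.  The rest
of the sequence is pseudo-random; it is NOT the rCRS and carries no
biological information beyond its coordinate system.
"""

from __future__ import annotations

import pathlib

import numpy as np

LENGTH = 16569

# (name, start, end, strand, kind) -- real rCRS gene coordinates, 1-based inclusive.
CODING_TABLE = [
    ("MT-TF", 577, 647, "+", "trna"),
    ("MT-RNR1", 648, 1601, "+", "rrna"),
    ("MT-TV", 1602, 1670, "+", "trna"),
    ("MT-RNR2", 1671, 3229, "+", "rrna"),
    ("MT-TL1", 3230, 3304, "+", "trna"),
    ("MT-ND1", 3307, 4262, "+", "protein"),
    ("MT-TI", 4263, 4331, "+", "trna"),
    ("MT-TQ", 4329, 4400, "-", "trna"),
    ("MT-TM", 4402, 4469, "+", "trna"),
    ("MT-ND2", 4470, 5511, "+", "protein"),
    ("MT-TW", 5512, 5579, "+", "trna"),
    ("MT-TA", 5587, 5655, "-", "trna"),
    ("MT-TN", 5657, 5729, "-", "trna"),
    ("MT-TC", 5761, 5826, "-", "trna"),
    ("MT-TY", 5826, 5891, "-", "trna"),
    ("MT-CO1", 5904, 7445, "+", "protein"),
    ("MT-TS1", 7446, 7514, "-", "trna"),
    ("MT-TD", 7518, 7585, "+", "trna"),
    ("MT-CO2", 7586, 8269, "+", "protein"),
    ("MT-TK", 8295, 8364, "+", "trna"),
    ("MT-ATP8", 8366, 8572, "+", "protein"),
    ("MT-ATP6", 8527, 9207, "+", "protein"),
    ("MT-CO3", 9207, 9990, "+", "protein"),
    ("MT-TG", 9991, 10058, "+", "trna"),
    ("MT-ND3", 10059, 10404, "+", "protein"),
    ("MT-TR", 10405, 10469, "+", "trna"),
    ("MT-ND4L", 10470, 10766, "+", "protein"),
    ("MT-ND4", 10760, 12137, "+", "protein"),
    ("MT-TH", 12138, 12206, "+", "trna"),
    ("MT-TS2", 12207, 12265, "+", "trna"),
    ("MT-TL2", 12266, 12336, "+", "trna"),
    ("MT-ND5", 12337, 14148, "+", "protein"),
    ("MT-ND6", 14149, 14673, "-", "protein"),
    ("MT-TE", 14674, 14742, "-", "trna"),
    ("MT-CYB", 14747, 15887, "+", "protein"),
    ("MT-TT", 15888, 15953, "+", "trna"),
    ("MT-TP", 15956, 16023, "-", "trna"),
]

# Positions pinned to their real rCRS bases (1-based).  These are the classic
# control-region landmarks used by U5-style motifs plus the poly-C tracts the
# default exclusion ranges cover, and the coding positions used in the packaged
# motif rules.
PINNED = {
    73: "A", 146: "T", 150: "C", 152: "T", 195: "T", 263: "A",
    # 303-315 poly-C tract (CCCCCCCTCCCCC), 316 G terminates the run
    303: "C", 304: "C", 305: "C", 306: "C", 307: "C", 308: "C", 309: "C",
    310: "T", 311: "C", 312: "C", 313: "C", 314: "C", 315: "C", 316: "G",
    # coding positions used by packaged motif rules / examples
    3197: "T", 5495: "T", 5656: "A", 7768: "A", 9293: "G",
    14793: "A", 15218: "A",
    # HVS-I landmarks
    16114: "C", 16129: "G",
    16180: "A", 16181: "A", 16182: "A", 16183: "A",
    16184: "C", 16185: "C", 16186: "C", 16187: "C", 16188: "C",
    16189: "T", 16190: "C", 16191: "C", 16192: "C", 16193: "C", 16194: "T",
    16223: "C", 16256: "C", 16270: "C", 16294: "C", 16298: "T",
    16311: "T", 16362: "T", 16399: "A", 16526: "G",
}


def build_sequence(seed: int = 12345) -> str:
    rng = np.random.default_rng(seed)
    # human mtDNA heavy-strand base composition
    bases = rng.choice(list("ACGT"), size=LENGTH, p=[0.31, 0.31, 0.13, 0.25])
    for pos, base in PINNED.items():
        bases[pos - 1] = base
    return "".join(bases)


def main() -> None:
    data = pathlib.Path(__file__).resolve().parents[1] / "src" / "mitorho" / "data"
    data.mkdir(parents=True, exist_ok=True)
    seq = build_sequence()
    with open(data / "rcrs_synthetic.fasta", "w") as fh:
        fh.write(">rCRS_synthetic synthetic stand-in, rCRS coordinate system, 16569 bp\n")
        for i in range(0, LENGTH, 70):
            fh.write(seq[i : i + 70] + "\n")
    with open(data / "mt_coding_table.tsv", "w") as fh:
        fh.write("name\tstart\tend\tstrand\tkind\tframe_offset\n")
        for name, start, end, strand, kind in CODING_TABLE:
            fh.write(f"{name}\t{start}\t{end}\t{strand}\t{kind}\t0\n")
    print(f"wrote {data / 'rcrs_synthetic.fasta'} ({LENGTH} bp) and coding table")


if __name__ == "__main__":
    main()
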