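"""Regenerate the bundled synthetic mitochondrial reference sequence.

The bundled FASTA (``src/mitopair/data/rcrs_synthetic.fasta``) is a
SYNTHETIC stand-in for the 16,569-bp rCRS: a fixed-seed random sequence
constrained so that

* every protein gene starts with ATG (read on its own strand), ends with a
  planted stop codon (TAA) when its length is a multiple of three, or with
  the documented incomplete stop bases (T / TA) otherwise, and contains no
  internal stop codon in its own reading frame where constraints permit;
* every variant position documented in the package's tests and fixtures
  carries the correct reference base, and the codons around documented
  coding variants reproduce the documented amino-acid changes;
* every haplogroup-panel marker position carries the panel's ref base.

Run from the repository root:  python scripts/build_synthetic_reference.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from mitopair.reference import GENOME_LENGTH, complement, load_gene_map

SEED = 20201027  # fixed; regeneration is byte-identical
OUT = Path(__file__).resolve().parents[1] / "src" / "mitopair" / "data" / "rcrs_synthetic.fasta"
PANEL = Path(__file__).resolve().parents[1] / "src" / "mitopair" / "data" / "haplogroup_panel.tsv"

STOPS = {"TAA", "TAG", "AGA", "AGG"}  # vertebrate mitochondrial stops

# single-base reference constraints: documented variant positions -> ref allele
NAMED_REF_BASES = {
    146: "T", 153: "A", 207: "G", 235: "A", 644: "A", 663: "A",
    1736: "A", 2641: "A", 3219: "G", 3535: "T", 3631: "T",
    4248: "T", 4824: "A", 5567: "T", 5581: "A", 5726: "T", 5777: "G",
    7124: "A", 8027: "G", 8292: "G", 8794: "C",
    10463: "T", 11221: "A", 13997: "G",
    15115: "T", 15496: "A", 15928: "G", 15995: "G",
    16111: "C", 16134: "C", 16150: "C", 16162: "A", 16163: "A",
    16189: "T", 16248: "C", 16261: "C", 16270: "A", 16290: "C",
    16294: "C", 16296: "C", 16319: "G", 16362: "T", 16519: "T", 16527: "C",
}
# note 16270: documented as C16270A in the source material? ref C.
NAMED_REF_BASES[16270] = "C"

# full codons planted so documented coding variants yield the documented
# amino-acid changes; keys are genome positions of the codon's first base
# in genome orientation
PLANTED_CODONS = {
    3394: "TAC",   # ND1: T3394C -> Y/H
    4821: "GTT",   # ND2: T4823C -> V/V
    6369: "TCC",   # CO1: C6371T -> S/S
    7389: "TAT",   # CO1: T7389C -> Y/H
    8429: "CTC",   # ATP8: T8430A -> L22H
    8438: "CAA",   # ATP8: A8439C -> Q25P
    10290: "GCC",  # ND3: G10290A -> A/T
    12628: "TGG",  # ND5: G12630A -> W/W (TGA is Trp in the mito code)
    13333: "GCC",  # ND5: G13333A -> A/T
    13966: "ACC",  # ND5: A13966G -> T/A
    14470: "TCC",  # ND6 (L-strand): genome TCC == coding GGA; T14470C -> G/G
    15830: "ATT",  # CYB: T15831C -> I/T
    15836: "ATT",  # CYB: A15836C -> I/L (ATT Ile; ATA is Met in the mito code)
}


def build() -> str:
    rng = np.random.default_rng(SEED)
    gmap = load_gene_map(include_reference=False)
    seq: list = [None] * (GENOME_LENGTH + 1)  # 1-based

    def plant(pos: int, base: str, what: str) -> None:
        if seq[pos] is not None and seq[pos] != base:
            raise SystemExit(f"constraint conflict at {pos}: {seq[pos]} vs {base} ({what})")
        seq[pos] = base

    for start, codon in PLANTED_CODONS.items():
        for i, b in enumerate(codon):
            plant(start + i, b, f"codon@{start}")
    for pos, base in NAMED_REF_BASES.items():
        plant(pos, base, "named ref")
    panel = pd.read_csv(PANEL, sep="\t")
    for row in panel.itertuples(index=False):
        plant(int(row.position), str(row.ref), f"panel {row.haplogroup}")

    # start / stop / incomplete-stop codons per protein gene
    for g in gmap.protein_genes:
        rem = g.length % 3
        if g.strand == "H":
            for i, b in enumerate("ATG"):
                plant(g.start + i, b, f"{g.name} start")
            if rem == 0:
                for i, b in enumerate("TAA"):
                    plant(g.end - 2 + i, b, f"{g.name} stop")
            elif rem == 1:
                plant(g.end, "T", f"{g.name} incomplete stop")
            else:
                plant(g.end - 1, "T", f"{g.name} incomplete stop")
                plant(g.end, "A", f"{g.name} incomplete stop")
        else:  # ND6: coding sequence is the reverse complement
            for i, b in enumerate("CAT"):  # revcomp of ATG at the 3' genome end
                plant(g.end - 2 + i, b, f"{g.name} start")
            if rem == 0:
                for i, b in enumerate("TTA"):  # revcomp of TAA
                    plant(g.start + i, b, f"{g.name} stop")

    # fill protein codons avoiding in-frame stops; genes ordered so that in
    # overlaps the downstream-extending gene's frame governs the shared bases
    for g in sorted(gmap.protein_genes, key=lambda f: -f.end):
        n_full = g.length // 3
        for ci in range(n_full):
            gpos = []
            for k in range(3):
                coding_pos = 3 * ci + k
                off = coding_pos if g.strand == "H" else g.length - 1 - coding_pos
                gpos.append(g.start + off)
            fixed = [seq[p] for p in gpos]
            if all(b is not None for b in fixed):
                continue
            for _ in range(200):
                trial = [
                    b if b is not None else "ACGT"[rng.integers(4)] for b in fixed
                ]
                codon = "".join(
                    t if g.strand == "H" else complement(t) for t in trial
                )
                is_stop = codon in STOPS
                planted_stop = ci == n_full - 1 and g.length % 3 == 0
                if planted_stop or not is_stop:
                    for p, b in zip(gpos, trial):
                        seq[p] = b
                    break
            else:
                raise SystemExit(f"could not fill codon {ci} of {g.name}")

    for p in range(1, GENOME_LENGTH + 1):
        if seq[p] is None:
            seq[p] = "ACGT"[rng.integers(4)]
    return "".join(seq[1:])


def verify(sequence: str) -> None:
    """Re-annotate every documented variant and assert the documented labels."""
    from mitopair.consequence import annotate, primary_consequence
    from mitopair.io import VariantKey
    from mitopair.reference import GeneticCode

    tmp = OUT.parent / "_tmp_ref.fasta"
    write_fasta(sequence, tmp)
    gmap = load_gene_map(fasta=str(tmp))
    tmp.unlink()
    code = GeneticCode.vertebrate_mitochondrial()

    expected = [
        (207, "G", "A", "regulatory", None),
        (3394, "T", "C", "missense", "Y/H"),
        (4823, "T", "C", "synonymous", "V/V"),
        (5567, "T", "C", "tRNA", None),
        (5581, "A", "G", "intergenic", None),
        (6371, "C", "T", "synonymous", "S/S"),
        (7389, "T", "C", "missense", "Y/H"),
        (10290, "G", "A", "missense", "A/T"),
        (10463, "T", "C", "tRNA", None),
        (12630, "G", "A", "synonymous", "W/W"),
        (13333, "G", "A", "missense", "A/T"),
        (13966, "A", "G", "missense", "T/A"),
        (14470, "T", "C", "synonymous", "G/G"),
        (15831, "T", "C", "missense", "I/T"),
        (15836, "A", "C", "missense", "I/L"),
        (15928, "G", "A", "tRNA", None),
        (15995, "G", "A", "tRNA", None),
        (16162, "A", "G", "regulatory", None),
        (16163, "A", "G", "regulatory", None),
        (16134, "C", "T", "dloop_noncoding", None),
    ]
    for pos, ref, alt, effect, aa in expected:
        cons = annotate(VariantKey(pos, ref, alt), gmap, code)
        prim = primary_consequence(cons)
        assert prim is not None, (pos, ref, alt)
        assert prim.effect == effect, (pos, prim)
        if aa is not None:
            assert prim.aa_change == aa, (pos, prim)
    # ATP8 spot checks with amino-acid numbering
    for pos, ref, alt, aa, aapos in [(8430, "T", "A", "L/H", 22), (8439, "A", "C", "Q/P", 25)]:
        cons = [c for c in annotate(VariantKey(pos, ref, alt), gmap, code) if c.feature_name == "ATP8"]
        assert cons and cons[0].aa_change == aa and cons[0].aa_position == aapos, cons
    print(f"verified {len(expected) + 2} documented annotations")


def write_fasta(sequence: str, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            ">rcrs_synthetic SYNTHETIC stand-in for the 16569 bp human "
            "mitochondrial reference (simulated sequence, fixed seed)\n"
        )
        for i in range(0, len(sequence), 70):
            fh.write(sequence[i : i + 70] + "\n")


if __name__ == "__main__":
    sequence = build()
    assert len(sequence) == GENOME_LENGTH
    verify(sequence)
    write_fasta(sequence, OUT)
    print(f"wrote {OUT} ({len(sequence)} bp)")
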