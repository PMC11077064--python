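#!/usr/bin/env python
"""Compositional dissimilarity versus linear-sequence similarity.

The central contrast: across a family of sequences that share amino-acid
composition but not residue order, the all-vs-all chi-score matrix sits
near 0 (compositional homology) while global-alignment similarity is no
better than each sequence aligned to scrambles of itself (no linear
homology). Writes chi_matrix.tsv and similarity_matrix.tsv (with the
scrambled-self "*" column) and prints the summary contrast.
"""

import argparse
from pathlib import Path

import numpy as np

from comphom import chi_score_matrix, read_fasta, similarity_matrix


def write_matrix(path, ids, values, extra_name=None, extra=None):
    with open(path, "w") as fh:
        header = ["id", *ids] + ([extra_name] if extra is not None else [])
        fh.write("\t".join(header) + "\n")
        for i, ident in enumerate(ids):
            row = [ident] + [f"{values[i, j]:.6f}" for j in range(len(ids))]
            if extra is not None:
                row.append(f"{extra[i]:.6f}")
            fh.write("\t".join(row) + "\n")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=20240302)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    seqs = read_fasta(args.results / "synthetic_family.fasta")
    k = len(seqs)

    chi = chi_score_matrix(seqs, include_reference=True)
    write_matrix(args.results / "chi_matrix.tsv", chi.ids, chi.values,
                 "ref_uniform", chi.reference_column)

    ids, _, simil, scr = similarity_matrix(seqs, with_scrambled=3, seed=args.seed)
    write_matrix(args.results / "similarity_matrix.tsv", ids, simil, "*", scr)

    iu = np.triu_indices(k, k=1)
    print(f"{k} sequences, {len(iu[0])} unique pairs")
    print(f"mean pairwise chi-score:        {chi.values[iu].mean():.4f} "
          f"(0 = identical composition)")
    print(f"mean score vs 5%-uniform ref:   {chi.reference_column.mean():.4f}")
    print(f"mean pairwise pct similarity:   {simil[iu].mean():.1f}%")
    print(f"mean scrambled-self baseline:   {scr.mean():.1f}%")
    print("=> composition conserved, residue order uninformative" if
          abs(simil[iu].mean() - scr.mean()) < 5 else
          "=> alignment similarity departs from the scrambled baseline")


if __name__ == "__main__":
    main()
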