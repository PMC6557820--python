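# tanglescan

Gaussian-entanglement analysis of protein backbones: detect loops that wind
around another portion of the same chain, quantify how often and on which
side they occur, and measure the sequence signatures they leave in
contact statistics.

## The problem

Most protein folds are stabilized by local contacts, and strongly knotted
topologies are rare. Yet many domains contain subtler *entangled motifs*: a
loop, closed by a non-covalent residue–residue contact, through which (or
around which) another stretch of the chain threads. Such motifs matter for
folding kinetics — a loop that forms too early can trap the chain — and for
cotranslational folding, where the N-terminal part of the chain folds first.
`tanglescan` implements a complete pipeline for finding and characterizing
these motifs in Cα traces, plus synthetic-structure generators with known
topological and statistical ground truth so every stage is testable without
downloading structure databases.

## The score

For two open subchains γ_i (residues i1..i2) and γ_j (j1..j2) of a Cα trace,
the mutual winding is the discretized Gauss double integral

```
G'(γ_i, γ_j) = (1/4π) Σ_{i=i1}^{i2-1} Σ_{j=j1}^{j2-1}
               (R_i − R_j) / |R_i − R_j|³ · (ΔR_i × ΔR_j)
```

with bond midpoints R_i = (r_i + r_{i+1})/2 and bond vectors
ΔR_i = r_{i+1} − r_i. For closed curves this sum approximates the integer
linking number; on open subchains it is a real number measuring their
entanglement, signed by the handedness of the winding.

The pipeline specializes this to *contact-closed loops*: γ_i is a loop if
its end residues have heavy atoms within 4.5 Å and i2 − i1 ≥ m0 = 10.
Maximizing |G'| over all threads γ_j (length ≥ m0, non-overlapping, on one
side of the loop) gives the per-loop score G'_c(i); a loop is *entangled*
when |G'_c(i)| ≥ 1, the minimum modulus at which two closed curves would be
linked. The per-protein extrema define the Gaussian entanglement G'_c (over
loop–thread pairs) and the linking entanglement L' (over loop–loop pairs),
with |L'| ≤ |G'_c| by construction.

Downstream statistics include:

* **Loop clustering** — near-duplicate entangled loops within one protein
  are collapsed by a greedy neighbor scheme with the distance
  `sqrt(Δi1² + Δi2² + Δj1² + Δj2² + w_g Δg²)` (d* = 20, w_g = 10⁴); each
  loop then counts with weight 1/N_C.
* **Thread-side asymmetry** — weighted fractions of N- vs C-terminal
  threads, an exactly-enumerated uniform random-thread reference, weighted
  KS comparison of separation distributions, and the chirality split
  (sign of G'_c(i)) per side.
* **Contact potentials** — quasi-chemical scores E_norm = −τ log(f_c/f) and
  E_GE for entangled-loop closures, the enrichment score
  ΔE_enr = E_GE − E_norm (τ = 100), protein-level bootstrap errors
  (101 resamples), and the ΔE_enr vs E_norm correlation report.
* **Ensemble comparison** — length-filtered, loop-length-stratified score
  histograms and RMS G'_c(i) between a reference set and a compact decoy
  ensemble.

## Worked example

Generate a synthetic chain whose loop winds +2 turns around a thread on its
N-terminal side, then scan it:

```python
from tanglescan import read_structure, protein_entanglement

trace = read_structure("fixtures/helix_wrap_t+2_N_0.pdb")
result = protein_entanglement(trace)
print(f"G'_c = {result.protein_ge:.3f}")
top = max((r for r in result.loops if r.has_thread), key=lambda r: abs(r.g))
print(f"best loop side = {top.side}, entangled = {top.entangled}")
```

prints

```
G'_c = 2.022
best loop side = N, entangled = True
```

i.e. the scan recovers the planted winding number (+2, within ~1%), flags
the loop as entangled, and classifies the thread as N-terminal. The same
run from the shell:

```
$ tanglescan simulate --kind helix_wrap --turns 2 --side N --outdir fixtures
$ tanglescan scan fixtures --loops-out loops.tsv --proteins-out proteins.tsv
1 proteins, 1 loops
```

with `loops.tsv` containing the per-loop record
(`i1=58 i2=94 j1=0 j2=41 side=N g=2.0218`). The other subcommands —
`cluster`, `asymmetry`, `potentials`, `compare` — consume these tables; see
`tanglescan --help`.

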