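# sslinker

Determination of protein disulfide (S-S) bond connectivity from tandem
mass spectrometry data, for proteomics practitioners who digest a
protein under non-reducing conditions and want the globally consistent
set of cysteine pairings — with confidence scores — out of a precursor
mass list and MS/MS peak lists.

The search space of disulfide-bonded peptide structures grows
exponentially (n!/((n/2)!·2^(n/2)) connectivity patterns over n bonded
cysteines; up to f^k fragment arrangements for k linked peptides over f
ion types), so `sslinker` never builds it.  Instead it runs a two-stage
approximate subset-sum search:

1. **Initial Match (IM):** masses of disulfide-bonded peptide
   structures (Σ peptide masses − 2·1.00783 Da per bond) are grown
   incrementally from the cysteine-containing peptides of an in-silico
   digest, pruned above `PMS_val + T_IM` and thinned by a
   (1+ε)-trimming step that guarantees every removed mass a retained
   representative within factor (1+ε); a precursor matches when the
   largest retained mass falls within ±T_IM (default 1.0 Da).
2. **Validation Match (VM):** for each IM, theoretical fragment
   structures over ten ion types (a, b, b°, b*, c, x, y, y°, y*, z) —
   with fragments spanning a bonded cysteine carrying their partner
   peptide — are matched against the MS/MS peaks within ±T_VM.

Each candidate bond is scored by the intensity-weighted match score

&nbsp;&nbsp;&nbsp;&nbsp;V_s = 100 · Σᵢ VMᵢ·I_N(i) / Σᵢ TMSᵢ·I_N(i)

(I_N = base-peak-normalized intensity; a peak matched by several
fragment structures counts once per match, so V_s can exceed 100),
plus binomial-tail (`pp`) and Monte-Carlo abundance (`pp2`) confidence
scores.  Bonds above threshold (80 multi-ion / 30 b/y-only) become
weighted edges on the cysteine graph, and the reported topology is its
maximum-weight matching, so no cysteine is assigned two bonds.

## Worked example

The first-stage search on a published operating point — 29
cysteine-containing-peptide masses, precursor 2050.5 Da, ε = 0.02530,
T_IM = 1.0 Da:

```python
from sslinker import Peptide, approx_dms

ccp = [Peptide.from_mass(m, n_cys=1) for m in
       [716, 728, 749, 863, 864, 891, 976, 1096, 1105, 1161, 1204, 1274,
        1359, 1367, 1418, 1480, 1593, 1733, 1754, 1846, 1863, 1864, 1976,
        2179, 2292, 2351, 2617, 2737, 2822]]
dms, im = approx_dms(ccp, pms_value=2050.5, epsilon=0.02530, t_im=1.0)
print(f"retained {len(dms.entries)} masses, trimmed {len(dms.trimmed)}")
print(f"IM: {im.structure.name} at {im.mass:.3f} Da (delta {im.delta:.3f})")
```

prints

```
retained 21 masses, trimmed 32
IM: m891 - m1161 at 2049.984 Da (delta 0.516)
```

i.e. the search discards most of the combined mass space yet declares
the Initial Match at 2050 Da — the 891 + 1161 Da peptide pair minus two
hydrogens — 0.516 Da from the precursor.  (With real sequences the 891
and 1161 Da peptides are CDEIHLY and KTCAVVGNSGIL, bonded C142–C292.)

End to end on simulated data with a known answer:

```sh
$ sslinker simulate --n-bonds 2 --seed 7 --out sim
simulated 2 bond(s) in a 65-residue protein
inputs + ground truth written to sim/
$ sslinker run --fasta sim/protein.fasta --pms sim/pms.txt --spectra sim --out results
... PMS 2179.97: eps=2.29e-04 DMS 9 retained / 0 trimmed, 1 IM, 400 VM (0.13s)
... PMS 2220.06: eps=2.25e-04 DMS 10 retained / 0 trimmed, 1 IM, 400 VM (0.10s)
2 scored bond(s); topology:
  C8-C48
  C33-C43
reports written to results/
```

which recovers exactly the planted topology in `sim/truth.json`
(cysteines 8–48 and 33–43, 1-based residue numbering).  `results/`
holds a `bonds.tsv` table (cysteine pair, V_s, pp, pp2, supporting VM
count) and a `summary.json` with the topology and per-precursor
search-space accounting (retained vs. trimmed counts per stage).
`sslinker eval --predicted results/summary.json --known sim/truth.json`
scores a prediction (sensitivity, specificity, accuracy, Matthews c).

The full model, parameter meanings and simulator scope are described in
[docs/methods.md](docs/methods.md).

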