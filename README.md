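# dyz1kit

In-silico analysis of human Y-chromosome **DYZ1** satellite arrays, built
for studies that ask how the male-specific region of the Y (MSY) and its
heterochromatic DYZ1 block fare in tumour genomes — for example in
prostate-cancer cell lines such as DU145 and LNCaP, where the MSY can
stay intact while DYZ1 accumulates substitutions, indels and copy-number
loss.

A DYZ1 HaeIII repeat unit (~3.4–3.56 kb, e.g. the unit of accession
AC068123.5) is built almost entirely of the pentanucleotide **TTCCA**
and its mutated derivatives. The toolkit covers the desk side of a full
characterisation:

- **Pentamer spectra** — tile a unit into in-frame pentamers, classify
  each by Hamming distance *d* to TTCCA (*d* = 0 exact, *d* = 1 the
  fifteen single-base derivatives, … up to *d* = 5), and compare spectra
  between arrays.
- **Virtual restriction digest** — IUPAC-aware site scanning over an
  editable enzyme panel, per-enzyme frequency tables, lost/gained-site
  comparison between a reference and a sample unit, and PCR-RFLP
  fragment prediction for allele typing.
- **Variant tallies** — affine-gap Needleman–Wunsch global alignment
  (or ingestion of an existing CLUSTAL/FASTA alignment), counting
  substitutions and merged indel events with the net length change.
- **STS deletion mapping** — in-silico PCR over a 51-marker sY panel
  and classification of presence/absence profiles against configurable
  AZF deletion signatures (AZFa, P5/proximal-P1, P5/distal-P1, AZFc,
  gr/gr, b1/b2, b2/b3, TSPY–TSPY).
- **qPCR absolute quantification** — fit the standard curve
  Ct = *b* + *m*·log₁₀(copies), derive amplification efficiency
  *E* = 10^(−1/m) − 1 and R², extrapolate unknowns, and normalise to
  copies per genome equivalent (3.3 pg).
- **Synthetic data** — seeded generators for every input class
  (arrays with known derivative composition, planted variants, dilution
  series with a known efficiency model, STS panels with planted
  deletion classes), each retaining its ground truth.

## Worked example

```python
import dyz1kit as dk

# a 3,560-base synthetic array (712 pentamer units) with realistic
# derivative rates, plus its exact ground-truth spectrum
array, truth = dk.generate_array(dk.ArraySpec(n_units=712, seed=1))

sp = dk.spectrum(array)
print(sp.total_length, sp.counts["TTCCA"], sp.by_distance[1])
# 3560 236 288     (712 units: 236 exact TTCCA, 288 one-base derivatives)

# plant the published style of events: a 15-bp insertion and a 114-bp
# deletion shrink the unit by a net 99 bp
mutated, planted = dk.inject_variants(
    array,
    dk.VariantPlan(n_substitutions=27,
                   indels=[("insertion", 1654, 15), ("deletion", 2541, 114)],
                   seed=2),
)
tally = dk.tally_from_alignment(dk.align_global(array, mutated))
print(tally.substitutions, tally.net_length_change)
# 27 -99            (all planted substitutions recovered; net loss 99 bp)

# a noise-free ten-fold dilution series at 100% efficiency gives the
# canonical standard curve
points = dk.simulate_dilution_series(dk.SeriesSpec(efficiency=1.0, noise_sd=0.0))
curve = dk.fit_standard_curve(points)
print(round(curve.slope, 2), round(curve.r_squared, 4), round(curve.efficiency, 3))
# -3.32 1.0 1.0
copies = dk.quantify(ct=25.0, curve=curve)
print(round(dk.copies_per_genome(copies, input_mass_pg=3.3)))
# 32768             (copies per 3.3 pg of input DNA at Ct 25)
```

The same stages are available from the shell:

```bash
dyz1kit --seed 1 simulate array --out demo
dyz1kit spectrum demo.fasta                 # spectrum table per array
dyz1kit compare-digest ref.fasta sample.fasta   # lost/gained enzymes
dyz1kit qpcr fit standards.tsv              # slope, R², efficiency
dyz1kit sts classify --profile profile.tsv  # AZF deletion classes
```

Bundled, editable data assets (under `src/dyz1kit/data/`): the 65-enzyme
virtual-digest panel, the PCR-RFLP enzyme set and published assay table,
the 51-marker sY panel, primer coordinate tables, published spectrum and
digest-frequency counts for AC068123.5/DU145/LNCaP, and a curated
deletion-signature config (see its `comment` fields — the signatures are
an editable approximation of the clinical deletion-mapping literature,
not hard-coded truth).

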