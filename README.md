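# acanthoflux

Tools for quantifying Acantharia — marine protists that build their
skeletons from celestite (SrSO₄) — in two complementary data streams:

1. **V9 18S rRNA metabarcoding.** Quality-filter amplicon reads, assign each
   read a taxonomic lineage by exact global pairwise alignment against a
   clade-annotated reference database, and summarize clade composition by
   sample and depth zone.
2. **Sediment-trap strontium fluxes.** Detect episodic pulses of sinking
   acantharian cysts as excess Sr in sequential trap bottles over the
   seawater background, convert them to Sr and organic-carbon fluxes with
   propagated uncertainties, and express the result as a share of the
   particulate-organic-carbon (POC) flux.

A synthetic-data module generates clade-structured references, error-bearing
quality-scored reads, and spiked trap-bottle series — each with
machine-readable truth — so the whole pipeline is testable offline.

## Methods at a glance

**Read retention.** A read is kept only if the forward primer matches
exactly at the 5′ end and the reverse-complemented reverse primer at the 3′
end (IUPAC degeneracy honored in the primer only), and no 50-bp sliding
window of per-base Phred error probabilities `p_i = 10^(−Q_i/10)` has a mean
strictly above 1%.

**Assignment.** Each retained read is aligned end-to-end to every reference
with affine-gap Needleman–Wunsch (defaults +5/−4 match/mismatch, −12/−2 gap
open/extend). Percent identity is `matches / alignment columns`, kept as an
exact rational. The read takes the full lineage of its highest-identity
reference; ties take the last common ancestor (longest shared root-first
prefix) of the tied lineages. Reads not strictly above 85% identity stay
unassigned; a stricter 97% screen picks out reads closely related to named
cyst reference sequences.

**Sr flux.** Per trap, background = mean Sr over bottles < 9 µg mL⁻¹;
a bottle is significant when its concentration exceeds mean + 2·SD. Then

    F_Sr = (c − c_bg) · V / 1000 / (A · T)      [mg Sr m⁻² d⁻¹]
    σ_F  = sqrt((0.01·c)² + SD_bg²) · V / 1000 / (A · T)

with bottle volume `V` (mL), trap collection area `A` (0.66 m²) and period
`T` (days). Carbon flux uses the cyst C:Sr mass ratio 0.120 ± 0.022 mg/mg,
relative errors combined in quadrature. A carbonate sanity bound converts a
measured Ca elevation (µg mL⁻¹) times ~1 mg Sr per g into the maximum Sr
that CaCO₃ dissolution could contribute.

## Worked example

```python
from acanthoflux import simulate, qc, assign, srflux

cfg = simulate.SimulationConfig(seed=7)          # 4 clades × 5 refs, 130 bp
refs, _ = simulate.generate_reference_set(cfg)
reads, truth = simulate.simulate_reads(refs, 200, cfg)
retained, counts = qc.run_qc(reads, qc.QCConfig())
for a in assign.assign_reads(retained[:3], refs):
    print(a.read_id, float(a.best_identity), str(a.lineage), a.status)
```

prints

```
read_000000 1.0                Acantharea;CladeD assigned
read_000001 0.9615384615384616 Acantharea;CladeD assigned
read_000002 0.9769230769230769 Acantharea;CladeD assigned
```

i.e. the first read is an exact match to a CladeD reference, the next two
carry sequencing errors (96.2% and 97.7% identity) but still assign to
their true clade. On the geochemistry side:

```python
series, t = simulate.simulate_trap_series(simulate.TrapSimConfig(seed=3))
bg, results = srflux.analyze_series(series)
print(bg.mean, bg.sd)                # 7.8957  0.3060  (µg Sr / mL)
for r in results:
    if r.significant:
        print(r.bottle_id, r.sr_flux, r.sr_flux_sd, r.c_flux)
```

```
B04 0.2162 0.0093 0.0259
B08 0.4345 0.0105 0.0521
```

The two spiked bottles (true fluxes 0.2164 and 0.4329 mg Sr m⁻² d⁻¹) are
the only ones flagged, and the recovered fluxes agree with truth well
within one propagated standard deviation. Converting measured Sr fluxes of
0.13–0.23 mg m⁻² d⁻¹ through the C:Sr ratio:

```python
lo, _ = srflux.estimate_carbon(0.13, 0.0)   # 0.0156
hi, _ = srflux.estimate_carbon(0.23, 0.0)   # 0.0276
srflux.truncate(lo, 3), srflux.truncate(hi, 3)   # (0.015, 0.027) mg C m⁻² d⁻¹
```

## Command line

```bash
acanthoflux simulate-refs  --seed 11 --fasta refs.fasta --taxonomy-out refs.tsv
acanthoflux simulate-reads --seed 11 --n-reads 2000 --fasta refs.fasta \
    --taxonomy refs.tsv --fastq reads.fastq --truth truth.tsv
acanthoflux qc     --fastq reads.fastq --out passed.fastq --counts qc.json
acanthoflux assign --fastq passed.fastq --fasta refs.fasta --taxonomy refs.tsv \
    --out assignments.tsv --threshold 0.85
acanthoflux simulate-trap --seed 11 --csv trap.csv --truth trap_truth.csv
acanthoflux srflux --trap trap.csv --out flux.csv
acanthoflux run-all --config config.yaml      # qc → assign → summarize (+ srflux)
```

Exit codes: 0 success, 2 configuration error, 3 data error. `run-all`
writes a manifest with input hashes and per-stage counts; identical config
and seed reproduce the output directory byte for byte.

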