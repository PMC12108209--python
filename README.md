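# redoxpheno

Quantitative analysis of ratiometric roGFP2 redox imaging and fluorescent-dye
seedling phenotyping, with a statistics layer (one-way ANOVA, Duncan's
multiple range test with compact letter display, Pearson correlation
matrices) and a synthetic-data generator for testing the whole chain against
known ground truth.

## Who this is for

Plant cell biologists and microscopists who measure the cytosolic glutathione
redox potential of seedlings with the roGFP2 biosensor, quantify ROS and
vitality dyes (DHE, H2DCFDA, FDA) in circular regions of interest on
wide-field images, score root architecture (primary root length, lateral root
count and density), and report group comparisons with Duncan letters and
trait correlations — typically across a wild type and a panel of mutant
genotypes under salt/osmotic stress treatments.

## The model

roGFP2 is read out as the excitation ratio `R = I405 / I488` of
background-corrected ROI mean intensities. With calibration ratios of the
fully reduced (10 mM DTT) and fully oxidized (20 mM H2O2) sensor, the degree
of oxidation is

```
OxD = (R − R_red) / [ (I488_red / I488_ox) · (R_ox − R) + (R − R_red) ]
```

and the glutathione redox potential follows from the Nernst equation

```
E_GSH = E0 − (1000 · ln10 · R · T) / (z · F) · log10((1 − OxD) / OxD)
```

with `E0 = −272 mV` (roGFP2 midpoint), `R = 8.315 J K⁻¹ mol⁻¹`,
`T = 298.15 K`, `z = 2`, `F = 96485 C mol⁻¹`, i.e. a decadic slope of
≈ 29.58 mV. More oxidized tissue ⇒ higher OxD ⇒ less negative `E_GSH`.

Dye intensities are ROI means reported as *control %* (the untreated
wild-type group mean maps to exactly 100 %). Lateral root density is visible
lateral roots per cm of primary root. Post-hoc comparisons use Duncan's
multiple range test: a span of `p` ordered means is tested against
`q_{1−(1−α)^(p−1)}(p, df) · sqrt(MSE / n)` with the containment rule, and
decisions are summarized as a compact letter display.

## Worked example

```python
from redoxpheno import CalibrationState, egsh_from_intensities

calib = CalibrationState(r_red=0.30, r_ox=2.10, i488_red=400.0, i488_ox=130.0)
ratio, oxd, egsh = egsh_from_intensities(250.0, 300.0, calib)
print(f"ratio = {ratio:.4f}  OxD = {oxd.oxd:.4f}  E_GSH = {egsh:.2f} mV")
```

prints

```
ratio = 0.8333  OxD = 0.1204  E_GSH = -297.55 mV
```

— an ROI with a 405/488 ratio of 0.83 between the calibration endpoints is
12 % oxidized, i.e. a cytosol at −297.6 mV, a typically reduced resting
state (the sensor midpoint −272 mV would correspond to 50 % oxidation).

Group comparisons on a simulated phenotyping experiment:

```python
from redoxpheno import fig8_preset, generate_phenotype_table, duncan_mrt

table = generate_phenotype_table(fig8_preset(n_per_group=45, seed=1))
ctrl = table[table["treatment"] == "control"]
groups = {g: s["primary_root_length"].to_numpy() for g, s in ctrl.groupby("genotype")}
print(duncan_mrt(groups).summary().to_string(index=False))
```

```
group      mean  n letters
gpxl3 51.312503 45       a
gpxl1 51.541397 45       a
gpxl7 57.406870 45       b
gpxl2 59.654978 45      bc
Col-0 61.020271 45      bc
gpxl5 61.204161 45       c
gpxl8 68.879112 45       d
gpxl4 69.511714 45       d
gpxl6 70.995275 45       d
```

Groups sharing a letter are not significantly different at p ≤ 0.05; here
the short-rooted mutants (`gpxl1`, `gpxl3`) separate cleanly from the
long-rooted ones (`gpxl4`, `gpxl6`, `gpxl8`), with the wild type in between.

The command line drives the same machinery:

```
redoxpheno simulate --outdir sim --seed 1           # synthetic TIFFs + phenotype CSV
redoxpheno redox    --config config.yaml            # per-genotype E_GSH table
redoxpheno stats    --config config.yaml            # ANOVA/Duncan/correlation report
redoxpheno all      --config config.yaml
```

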