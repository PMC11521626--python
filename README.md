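# shearlog

Light-level geolocation, saltwater-immersion behaviour classification and
carry-over statistical inference for archival seabird loggers, with a
ground-truthed simulator of multi-year trans-equatorial tracking studies.

## The problem

Small archival loggers (geolocators) record ambient light and saltwater
immersion for years on a bird's leg. From nothing but those two channels a
movement ecologist can reconstruct, for a trans-equatorial migrant such as
the Manx shearwater (*Puffinus puffinus*):

* **daily position** — twilight events are the times the light trace
  crosses a fixed threshold (10 logger units); day length between a
  sunrise/sunset pair gives latitude through the sunrise equation,
  `cos H = (sin a − sin φ sin δ) / (cos φ cos δ)`, at a per-track
  calibrated sun elevation angle `a ∈ [−5, −3]`, and the midpoint of the
  pair gives longitude from its offset to Greenwich apparent noon;
* **behaviour** — each 10-min immersion score (0–200 wet 3-s samples)
  maps to flight (0), rest on the water (200) or foraging (in between);
  a ≥ 6 h daytime dry spell means the bird is in its burrow, a ≥ 3 day dry
  spell is an incubation stint, and nights ashore are separated from
  nights at sea by a two-component Gaussian EM mixture over nightly
  wet-event counts;
* **migration phenology** — departure and return dates from sustained
  longitude displacement (longitude is immune to equinox error);
* **carry-over inference** — a recursive path analysis linking a
  Southern-Oscillation-like climate index to non-breeding latitude,
  foraging effort and the next breeding season's effort and chick
  provisioning, plus van de Pol & Wright subject centring to split the
  latitude response into within- and between-individual components, and
  random-intercept mixed models with likelihood-ratio tests and
  parametric-bootstrap confidence intervals.

Because multi-year raw logger archives are large and access-restricted,
the package ships a first-class simulator (`shearlog.synthio`) that
generates bird-years with known ground truth — light consistent with solar
elevation along the true track plus shading, immersion from a day/night
Markov behaviour process with colony visits and incubation, an AR(1)
climate index that shifts winter latitude with a programmed
within-individual slope, and January chlorophyll fields with a programmed
zonal ridge — so every stage is testable end to end.

## Worked example

The numbered drivers under `analysis/` run the whole study on simulated
data (10 birds, 2–4 logger-years each) and write tables under `results/`:

```sh
cd analysis
python 01_simulate.py
python 02_geolocate.py
python 06_infer.py
```

prints, among other things:

```
bird-years simulated: 29 from 10 birds
within-individual slope on truth: -0.270 deg per index unit (programmed -0.30)

median |latitude error|:  0.108 deg
median |longitude error|: 0.132 deg
calibrated sun elevation angles: {-4.0: 29}

within-individual latitude slope:  -0.260 CI (-0.461, -0.069) (programmed -0.30)
January latitude vs chlorophyll-peak latitude: beta 0.102, LRT p 0.0173
```

Read: geolocation recovers the true track to ~0.1° away from equinoxes
and the calibration picks exactly the sun elevation angle the light was
generated with; the subject-centring mixed model recovers the programmed
within-individual latitude response to the climate index from the fully
processed sensor data, and birds track the simulated chlorophyll ridge.

The same pipeline is scriptable (`shearlog run --seed 1 --out-dir run/`)
and each stage is exposed as a subcommand (`simulate`, `geolocate`,
`phenology`); stages cache their CSV artifacts under a manifest, so
re-runs only recompute what changed.

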