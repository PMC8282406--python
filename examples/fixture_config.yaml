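# Configuration of the bundled documentation fixture. The fixture itself is
# regenerated deterministically by iemv.bundled_fixture() (or the CLI call
# below); it is not stored, so examples can never drift from the generator.
#
#   iemv synth --seed 17 --n-per-group 3 --n-aux 3 --out fixture/
seed: 17
n_countries_per_group: 3
n_aux_countries: 3
noise_sd: 0.02
years: [2010, 2030]
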