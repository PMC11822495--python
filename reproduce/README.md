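# Reproduction configs

One experiment config per stimulation system, runnable as

    protact run --config reproduce/lorenz.json --outdir scratch/repro_lorenz

Each chains drive generation -> response surrogate -> the full analysis
suite -> OTL gating, with every seed explicit.  To analyze recorded
(deposited) traces instead of the surrogate, point the config's
`response_path` at an unpacked recording exported as two-column
`time_s,voltage_V` CSV (the reader also auto-detects headerless TSV),
and run `protact analyze --in <input.csv> --paired <output.csv>` for
pairwise characterization.  The deposit's internal layout is not scripted
here; its sampling interval is inferred from the files on read.
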