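# File formats

All text files are whitespace- or comma-delimited as noted; binary
containers are HDF5.

## Genotypes

**raw-matrix** (default): whitespace-delimited integers, one row per
individual, one column per marker, entries in {0, 1, 2}, no header.

**plink-raw**: PLINK `.raw` additive export.  Header line
`FID IID PAT MAT SEX PHENOTYPE <marker> <marker> ...`; the six leading
columns are skipped on read (IID is kept as the individual id), marker
names are retained from the header.  `NA` or any non-{0,1,2} code is
rejected with the row/column of the first offending entry.

## Phenotypes

CSV with header `id,y,bv`: individual id, phenotype, true breeding value
(simulated data; `bv` column may be absent in real data, only `id` and
`y` are required on read).

## QTL truth table

CSV with header `locus,effect`: locus index in the original (pre-
filtering) coordinate system and the scaled effect size.

## Column means

`train.colmeans.txt`: one float per kept marker (training-set column
means), written by `bayesxii simulate`, consumed via `--colmeans` to
center test matrices consistently.

## Chain trace

`<prefix>.scalars.csv`: header
`iteration,mu,pi,sigma2_a,sigma2_e,n_included`, one row per iteration
(iteration starts at 1).

`<prefix>.effects.h5`: attributes `version`, `length`, `thin`, `seed`,
`chain_index`, `variant`; datasets `a_samples` (thinned marker-effect
samples, rows at iterations thin, 2·thin, ...), `a_mean` (running mean
over all iterations), `initial_a`.  Read errors on version mismatch or
truncation.

## Augmentation

HDF5 with attributes `version`, `d`, `jitter`, optional `source_hash`
(SHA-1 of the centered genotype matrix used to build it); datasets
`J_tilde` (p+1 vector), `X_tilde` ((p+1) × p).

## Run configuration

Flat `key = value` text, `#` comments; keys mirror the `run` command's
flags with `-` or `_` interchangeable (`genotypes`, `phenotypes`,
`colmeans`, `method`, `aug`, `length`, `out_dir`).  Command-line flags
override file values.
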