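>xa2_peptide murine 18.5 kDa MBP residues S38-S107 start=38
SIGRFFSGDRGAPKRGSGKDSHTRTTHYGSLPQKSQHGRTQDENPVVHFFKNIVTPRTPP
PSQGKGRGLS
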