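# rDNA feature table for the human KY962518.1 reference (44,838 nt).
# Coordinates are 0-based half-open in ORIGINAL (unrotated) reference
# coordinates; the build rotates them onto chrR automatically.
#
# These are APPROXIMATE defaults assembled from the rDNA literature.
# Confirm or edit them against your annotation source before relying on
# them for interpretation; TTF1 binding sites in particular must be
# supplied by the user (none are shipped).
#
# columns: name <TAB> class <TAB> start <TAB> end <TAB> color(optional R,G,B)
5ETS	ets	0	3657
18S	mature_rrna	3657	5527
ITS1	its	5527	6623
5.8S	mature_rrna	6623	6780
ITS2	its	6780	7935
28S	mature_rrna	7935	13357
IGS	igs	13357	44538
spacer_promoter	promoter	44538	44688
47S_promoter	promoter	44688	44838
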