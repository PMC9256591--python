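species	coi_bin	coi_asap	coi_ptp	coi_gmyc	coi_kot4	coi_kot5	coi_pdt	s16_asap	s16_ptp	s16_gmyc	s16_kot4	s16_kot5
Akerogammarus sp.	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK
Amathillina cristata	OK	OK	OK	OK	S	S	OK	L	L	L	S+L	L
Amathillina pusilla	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK
Amathillina spinosa	NA	NA	NA	NA	NA	NA	NA	L	L	L	L	L
Chaetogammarus hyrcanus	OK	OK	S	OK	S	S	OK	OK	OK	S	S	S
Chaetogammarus ischnus	S	L	L	L	S+L	S+L	L	L	L	L	L	L
Chaetogammarus placidus	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK
Chaetogammarus sp.	OK	OK	OK	OK	S	S	OK	OK	OK	OK	S	OK
Chaetogammarus warpachowskyi	S	S	S	S	S	S	OK	OK	S	S	S	S
Chelicorophium chelicorne	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK
Chelicorophium curvispinum	S	L	S+L	L	S+L	L	L	L	L	S+L	S+L	L
Chelicorophium maeoticum	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK
Chelicorophium monodon	L	L	L	L	L	L	L	L	L	L	S+L	L
Chelicorophium mucronatum	S+L	S+L	S+L	S+L	S+L	L	S+L	L	L	L	S+L	L
Chelicorophium nobile	OK	OK	OK	OK	S	S	OK	OK	OK	OK	OK	OK
Chelicorophium robustum	S	OK	S	S	S	S	OK	OK	S	S	S	S
Chelicorophium sowinskyi	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK
Dikerogammarus bispinosus	S	S	S	S	S	S	S	S	S	S	S	S
Dikerogammarus caspius	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK
Dikerogammarus haemobaphes	S	S	S	S	S	S	S	L	L	L	L	L
Dikerogammarus oskari	NA	NA	NA	NA	NA	NA	NA	L	L	L	L	L
Dikerogammarus villosus	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK
Echinogammarus karadagiensis	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK
Echinogammarus mazestiensis	OK	OK	OK	OK	S	OK	OK	NA	NA	NA	NA	NA
Gammaracanthus caspius	OK	OK	OK	OK	OK	OK	OK	NA	NA	NA	NA	NA
Gmelina aestuarica	OK	OK	OK	OK	OK	OK	L	NA	NA	NA	NA	NA
Gmelina costata	OK	OK	OK	OK	S	S	L	OK	OK	OK	OK	OK
Gmelinopsis tuberculata	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK
Jugogammarus kusceri	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK
Lanceogammarus andrussovi	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK
Monoporeia microphtalma	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK
Niphargogammarus aequimanus	L	L	L	L	OK	L	L	NA	NA	NA	NA	NA
Niphargogammarus quadrimanus	L	L	L	L	OK	L	L	OK	OK	OK	OK	OK
Obesogammarus boeoticus	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK
Obesogammarus crassus	OK	OK	OK	OK	S	S	OK	OK	OK	OK	S	OK
Obesogammarus obesus	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK
Obesogammarus platycheir	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK
Obesogammarus subnudus	OK	OK	OK	OK	S	OK	OK	OK	OK	OK	OK	OK
Onisimus caspius	S	OK	S	OK	S	S	OK	OK	OK	OK	OK	OK
Paraniphargoides motasi	OK	OK	OK	OK	OK	OK	OK	NA	NA	NA	NA	NA
Pontogammarus abbreviatus	L	L	L	L	L	L	L	L	S+L	L	L	L
Pontogammarus aestuarius	OK	OK	OK	OK	OK	OK	OK	OK	OK	L	OK	OK
Pontogammarus borceae	S+L	S+L	S+L	S+L	S+L	S+L	S+L	L	S+L	S+L	S+L	S+L
Pontogammarus cf. aestuarius	L	L	L	L	L	L	L	L	L	L	L	L
Pontogammarus maeoticus	S	S	S	S	S	S	S	S	S	S	S	S
Pontogammarus robustoides	L	L	L	L	L	L	L	L	L	L	L	L
Pontogammarus sarsi	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK
Pontogammarus setosus	OK	L	OK	L	S+L	S+L	L	L	L	OK	L	L
Shablogammarus shablensis	NA	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK
Stenogammarus similis	S	S	S	S	S	S	S	OK	S	S	S	S
Stenogammarus compressosimilis	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK
Stenogammarus sp.	OK	OK	OK	OK	OK	OK	OK	NA	NA	NA	NA	NA
Trichogammarus cf. trichiatus (Europe)	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK
Trichogammarus trichiatus (Caucasus)	S+L	L	L	L	S+L	S+L	L	L	L	L	L	L
Turcogammarus spandli	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK
Wolgagammarus dzjubani	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK	OK
Yogmelina cf. limana	NA	NA	NA	NA	NA	NA	NA	OK	OK	OK	OK	OK
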