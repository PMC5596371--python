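taxon,subfamily,reference,diploid_2n,formula,size_min_um,size_max_um,hcl_um,a2,tf,ask,syi,a1,a_watanabe
Paphiopedilum dianthum,Cypripedioideae,LA11,26,18M+8S,9.34,22.22,395.88,0.23,0.41,0.59,69.06,0.30,0.18
Paphiopedilum emersonii,Cypripedioideae,LA11,26,20M+4S+2A,5.06,12.56,204.98,0.24,0.40,0.60,66.36,0.31,0.20
Paphiopedilum hangianum,Cypripedioideae,LA11,26,22M+4S,9.66,18.11,325.92,0.20,0.44,0.56,80.04,0.18,0.11
Paphiopedilum micranthum,Cypripedioideae,LA11,26,16M+8S+2A,7.27,22.47,296.44,0.35,0.40,0.60,66.19,0.28,0.20
Paphiopedilum niveum,Cypripedioideae,LA11,26,20M+6S,6.46,18.35,255.90,0.27,0.45,0.55,80.99,0.19,0.11
Paphiopedilum randsii,Cypripedioideae,LA11,26,18M+8S,10.74,22.48,377.84,0.24,0.44,0.56,78.63,0.21,0.12
Paphiopedilum sukhakulii,Cypripedioideae,LA11,40,24M+16S,6.42,18.84,391.64,0.31,0.41,0.59,69.99,0.30,0.18
Paphiopedilum superbiens,Cypripedioideae,LA11,36,22M+14S,7.33,20.78,385.86,0.30,0.40,0.60,68.06,0.30,0.19
Phragmipedium sargentianum,Cypripedioideae,FG05,22,14M+8S,2.94,6.49,100.24,0.28,0.42,0.58,73.07,0.27,0.16
Acianthera recurva,Epidendroideae,OL15,52,38M+14S,1.08,2.05,76.78,0.15,0.44,0.56,77.20,0.22,0.13
Brasiliorchis gracilis,Epidendroideae,MO12,40,19M+21S,2.39,4.87,148.92,0.18,0.40,0.60,66.81,0.33,0.20
Brassavola nodosa,Epidendroideae,FG10,40,16M+24S,1.06,2.11,63.52,0.15,0.39,0.61,64.24,0.35,0.22
Campylocentrum crassirhizum,Epidendroideae,FG10,38,12M+24S+2A,0.87,1.56,48.56,0.13,0.37,0.63,57.53,0.41,0.27
Campylocentrum neglectum,Epidendroideae,DA09,38,20M+18S,0.62,1.20,33.64,0.19,0.40,0.60,65.91,0.33,0.21
Catasetum purum,Epidendroideae,FG00,54,32M+22S,0.93,3.09,93.10,0.25,0.41,0.59,69.53,0.29,0.18
Cattleya bradei,Epidendroideae,Y06,40,24M+16S,1.09,2.53,75.70,0.16,0.40,0.60,67.40,0.32,0.19
Cattleya cernua,Epidendroideae,DA09,40,18M+16S+6A,0.92,2.41,63.14,0.25,0.36,0.64,56.25,0.39,0.28
Cephalanthera damasonium,Epidendroideae,MS07,36,14M+14S+8A,2.46,16.0,219.36,0.60,0.29,0.71,40.32,0.44,0.43
Cephalanthera longifolia,Epidendroideae,MS07,32,12M+16S+4A,2.68,9.82,146.90,0.47,0.33,0.67,50.13,0.40,0.33
Cephalanthera rubra,Epidendroideae,MS07,44,14M+30S,2.43,12.52,230.94,0.49,0.36,0.64,57.07,0.38,0.27
Christensonella pachyphylla,Epidendroideae,K08,38,20S+18A,2.17,4.35,119.86,0.17,0.26,0.74,34.36,0.64,0.49
Christensonella paranaensis,Epidendroideae,K08,36,20M+16S,1.92,3.31,95.28,0.13,0.40,0.60,68.02,0.30,0.19
Christensonella pumila,Epidendroideae,K08,36,16M+18S+2A,2.02,3.38,97.78,0.12,0.37,0.63,59.49,0.37,0.25
Christensonella subulata,Epidendroideae,K08,38,4M+20S+14A,1.90,3.34,92.80,0.14,0.28,0.72,39.23,0.59,0.44
Dimerandra emarginata,Epidendroideae,FG10,40,28M+12S,0.86,2.14,60.60,0.20,0.43,0.57,75.47,0.24,0.14
Encyclia flava,Epidendroideae,FG10,40,10M+28S+2A,1.31,3.59,90.54,0.22,0.37,0.63,58.12,0.42,0.26
Encyclia oncidioides,Epidendroideae,FG10,40,16M+22S+2A,1.28,2.71,75.38,0.16,0.37,0.63,59.87,0.39,0.25
Epidendrum denticulatum,Epidendroideae,AS13,38,28M+6S+4A,1.0,3.05,65.46,0.26,0.43,0.57,75.47,0.24,0.14
Epidendrum fulgens,Epidendroideae,AS13,24,14M+8S+2A,1.10,3.01,36.26,0.29,0.40,0.60,68.03,0.32,0.18
Epidendrum latilabre,Epidendroideae,FG10,40,6M+34S,1.10,2.10,62.62,0.13,0.36,0.64,55.69,0.44,0.28
Epidendrum paniculatum,Epidendroideae,AS13,40,20M+16S+4A,1.08,2.26,66.48,0.17,0.39,0.61,64.29,0.34,0.22
Erycina pusilla,Epidendroideae,FG99,12,8M+4A,2.85,5.46,45.90,0.21,0.34,0.66,52.21,0.39,0.31
Mormolyca rufescens,Epidendroideae,FG00,40,30M+10S,1.04,2.02,62.98,0.18,0.42,0.58,73.55,0.25,0.15
Pabstiella fusca,Epidendroideae,OL15,28,14M+14S,0.62,1.32,27.78,0.17,0.39,0.61,65.16,0.32,0.21
Prosthechea fragrans,Epidendroideae,FG10,40,18M+22S,1.04,2.06,55.82,0.15,0.39,0.61,64.32,0.35,0.22
Sobralia liliastrum,Epidendroideae,FG10,48,34M+14S,1.51,4.15,109.52,0.27,0.43,0.57,74.20,0.25,0.15
Specklinia grobyi,Epidendroideae,OL15,20,18M+2A,0.88,2.07,30.66,0.20,0.45,0.55,80.57,0.20,0.11
Stelis sp.,Epidendroideae,FG10,32,12M+20S,0.73,1.35,29.38,0.18,0.38,0.62,60.40,0.38,0.25
Trichocentrum cebolleta,Epidendroideae,FG00,36,20M+14S+2A,1.79,2.91,79.38,0.14,0.40,0.60,66.31,0.31,0.20
Trichocentrum fuscum,Epidendroideae,FG00,20,8M+12S,2.38,4.87,73.46,0.21,0.39,0.61,64.80,0.33,0.21
Trichocentrum pumilum,Epidendroideae,FG00,30,19M+11S,2.47,6.75,128.94,0.25,0.41,0.59,70.45,0.28,0.17
Xylobium foveatum,Epidendroideae,FG00,40,26M+14S,1.84,3.88,114.84,0.20,0.41,0.59,70.64,0.28,0.17
Zygostates alleniana,Epidendroideae,DA09,54,36M+18S,1.0,2.72,80.92,0.27,0.41,0.59,70.93,0.26,0.17
Aspidogyne kuczynskii,Orchidoideae,DA09,42,24M+18S,0.64,1.46,45.24,0.15,0.41,0.59,69.69,0.29,0.18
Cyclopogon calophyllus,Orchidoideae,GR13,28,22M+6S,1.87,4.01,70.50,0.20,0.43,0.57,76.09,0.23,0.14
Cyclopogon chloroleucus,Orchidoideae,FG05,36,32M+4S,1.50,4.80,91.30,0.30,0.44,0.56,79.12,0.19,0.12
Cyclopogon congestus,Orchidoideae,MA84,32,8M+24S,0.86,2.77,56.56,0.28,0.37,0.63,58.05,0.42,0.27
Cyclopogon elatus,Orchidoideae,FG05,28,24M+4S,1.69,3.39,65.32,0.18,0.44,0.56,78.28,0.21,0.12
Cyclopogon elatus,Orchidoideae,GR13,28,18M+10S,1.87,4.26,75.34,0.19,0.43,0.57,75.49,0.23,0.14
Eltroplectris calcarata,Orchidoideae,MN16,42,22M+18S+2A,1.93,9.79,122.26,0.53,0.35,0.65,54.96,0.36,0.29
Eurystyles actinosophila,Orchidoideae,DA09,56,32M+20S+4A,1.04,2.02,77.32,0.17,0.40,0.60,66.32,0.32,0.20
Eurystyles sp.,Orchidoideae,MN16,14,12M+2S,1.63,3.17,31.40,0.23,0.45,0.55,80.98,0.19,0.11
Habenaria bicornis,Orchidoideae,BA14,42,22M+20S,3.63,6.83,214.24,0.13,0.41,0.59,68.18,0.31,0.19
Habenaria josephensis,Orchidoideae,MN16,50,34M+2S+14A,1.67,4.97,161.44,0.29,0.41,0.59,68.68,0.33,0.19
Mesadenella cuspidata,Orchidoideae,MN16,46,32M+12S+2A,1.86,4.38,106.46,0.21,0.40,0.60,68.05,0.28,0.19
Pelexia laxa,Orchidoideae,MA84,46,18M+28S+2A,0.88,2.63,56.98,0.27,0.36,0.64,56.20,0.41,0.28
Pelexia viridis,Orchidoideae,FG05,46,36M+8S+2A,1.30,4.72,92.52,0.30,0.41,0.59,70.62,0.25,0.17
Prescottia plantaginea,Orchidoideae,MN16,46,42M+4S,1.20,2.66,82.38,0.17,0.45,0.55,82.31,0.17,0.10
Pteroglossa lurida,Orchidoideae,MA84,46,12M+32S+2A,0.75,4.32,52.76,0.60,0.33,0.67,49.59,0.43,0.34
Sacoila lanceolata,Orchidoideae,MN16,46,40M+4S+2A,1.65,8.34,109.02,0.46,0.41,0.59,70.73,0.21,0.17
Sarcoglottis grandiflora,Orchidoideae,MN16,46,44M+2S,1.42,3.49,85.12,0.21,0.47,0.53,87.37,0.11,0.07
Vanilla pompona,Vanillioideae,FG05,32,10M+20S+2A,1.04,3.36,63.26,0.26,0.37,0.63,57.88,0.39,0.27
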