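article_id,trial_label,region,year,treatment_1,treatment_2,size_1,size_2,outcomes,row
peng_2013,Peng (2013),China,2013,TACE+RFA,RFA,94,95,1234,main
muhammad_2013,Adnan Muhammad (2013),USA,2013,TACE+SOR,TACE,13,30,1234,main
bai_2013,Wei Bai (2013),China,2013,TACE+SOR,TACE,82,164,12,main
nicolini_2013,Nicolini (2013),Italy,2013,DEB-TACE,TACE,22,16,1234,main
moreno_luna_2013,Moreno-Luna (2013),USA,2013,TARE-90Y,TACE,61,55,1234,main
qu_2012,Xu-Dong Qu (2012),China,2012,TACE+SOR,TACE,45,45,1234,main
song_2012,Song (2012),Korea,2012,DEB-TACE,TACE,60,69,123,main
recchia_2012,Recchia (2012),Italy,2012,DEB-TACE,TACE,35,70,123,main
peng_2011,Peng (2011),China,2011,TACE+RFA,RFA,69,70,1234,main
kudo_2011,Masatoshi Kudo (2011),Japan+South Korea,2011,TACE+SOR,TACE,229,229,123,main
song_2011,Song (2011),Korea,2011,DEB-TACE,TACE,20,20,123,main
salem_2011,Salem (2011),USA,2011,TARE-90Y,TACE,123,122,1234,main
wiggerman_2011,Wiggerman (2011),Germany,2011,DEB-TACE,TACE,22,22,123,main
sacco_2011,Sacco (2011),Italy,2011,DEB-TACE,TACE,33,34,123,main
malagari_2011,Malagari (2011),Greece,2011,DEB-TACE,TACE,41,43,1,main
kim_2010,Kim (2010),Korea,2010,TACE+RFA,RFA,83,231,1234,main
morimoto_2010,Morimoto (2010),Japan,2010,TACE+RFA,RFA,19,18,1234,main
li_2010,Li (2010),China,2010,TACE+HIFU,TACE,44,45,1234,main
tan_2010,Tan (2010),China,2010,TACE+SOR,TACE,10,10,12,main
kooby_2010,Kooby (2010),USA,2010,TARE-90Y,TACE,27,44,1234,main
carr_2010,Carr (2010),USA,2010,TARE-90Y,TACE,99,691,123,main
ferrer_puchol_2010,Ferrer Puchol (2010),Spain,2010,DEB-TACE,TACE,47,25,1234,main
dhanasekaran_2010,Dhanasekaran (2010),USA,2010,DEB-TACE,TACE,45,26,12,main
shibata_2009,Shibata (2009),Japan,2009,TACE+RFA,TACE,46,43,234,main
yang_2009,Yang-a (2009),China,2009,TACE+RFA,RFA,31,37,1234,a
yang_2009,Yang-c (2009),China,2009,RFA,TACE,37,35,1234,c
yang_2009,Yang-b (2009),China,2009,TACE+RFA,TACE,31,35,1234,b
cheng_2008,Cheng-b (2008),China,2008,TACE+RFA,TACE,96,95,1234,b
cheng_2008,Cheng-a (2008),China,2008,TACE+RFA,RFA,96,100,1234,a
cheng_2008,Cheng-c (2008),China,2008,RFA,TACE,100,95,1234,c
brunello_2008,Brunello (2008),Italy,2008,RFA,PEI,70,69,1234,main
wu_2005,Wu (2005),China,2005,TACE+HIFU,TACE,24,26,12,main
becker_2005,Becker (2005),Germany,2005,TACE+PEI,TACE,27,25,123,main
shiina_2005,Shiina (2005),Japan,2005,RFA,PEI,118,114,1234,main
lin_2005,Lin (2005),Taiwan,2005,PAI,PEI,63,62,123,main
shim_2005,Shim (2005),Korea,2005,TACE+RT,TACE,38,35,1234,main
lin_2004,Lin-a (2004),Taiwan,2004,RFA,PEI,50,46,123,a
lin_2004,Lin-b (2004),Taiwan,2004,RFA,PEI,50,50,123,b
zeng_2004,Zeng (2004),China,2004,TACE+EBRT,TACE,54,149,1234,main
lencioni_2003,Lencioni (2003),Italy,2003,RFA,PEI,52,50,123,main
guo_2003,Guo (2003),China,2003,TACE+RT,TACE,76,89,1234,main
kamada_2002,Kamada (2002),Japan,2002,TACE+PEI,TACE,32,37,1234,main
koda_2001,Koda (2001),Japan,2001,TACE+PEI,PEI,26,26,234,main
cheng_2001,Chia-Hsien Cheng-b (2001),China,2001,TACE+RT,RT,17,9,1234,b
cheng_2001,Chia-Hsien Cheng-c (2001),China,2001,RT,TACE,9,16,1234,c
cheng_2001,Chia-Hsien Cheng-a (2001),China,2001,TACE+RT,TACE,17,16,1234,a
allgaier_1998,Allgaier-b (1998),Germany,1998,TACE+PEI,TACE,39,33,12,b
allgaier_1998,Allgaier-a (1998),Germany,1998,TACE+PEI,PEI,39,15,12,a
allgaier_1998,Allgaier-c (1998),Germany,1998,PEI,TACE,15,33,12,c
bartolozzi_1995,Bartolozzi (1995),Italy,1995,TACE+PEI,TACE,26,27,123,main
kato_1994,Kato (1994),Japan,1994,TACE+PEI,TACE,24,22,123,main
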